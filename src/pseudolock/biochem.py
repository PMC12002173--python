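"""Phosphatase-assay scoring and cysteine-accessibility calling.

Covers the quantitative logic of two colorimetric phosphatase assays and
one mass-spectrometry labeling experiment:

* malachite-green endpoint assays — a phosphate calibration line converts
  A620 readings into mol product, a 3-SD blank rule decides
  detectability, and endpoint rates come out in mol product / min;
* pNPP kinetic assays — initial rates are the slope of the longest
  linear prefix (r^2-qualified) of an A405 time course;
* okadaic-acid attribution — when inhibitor treatment removes (nearly)
  all activity from a preparation that contains the putative enzyme in
  molar excess over the inhibitor, the activity is attributed to a
  contaminating okadaic-acid-sensitive phosphatase, not to the enzyme;
* MMTS:IAA differential alkylation — the within-row log2 intensity ratio
  of denatured-state (MMTS) to native-state (IAA) labeling classifies a
  cysteine as buried, exposed or intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError

__all__ = [
    "AssayTimeCourse",
    "Calibration",
    "fit_calibration",
    "endpoint_rate",
    "timecourse_rate",
    "oa_attribution",
    "alkylation_accessibility",
]


@dataclass
class AssayTimeCourse:
    """An absorbance time course for one enzyme dilution."""

    times: np.ndarray  # seconds, strictly increasing
    absorbance: np.ndarray
    enzyme_conc: float = 0.0  # molar
    inhibitor_conc: float = 0.0  # molar; 0 = untreated
    blanks: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.blanks = np.asarray(self.blanks, dtype=float)
        if len(self.times) != len(self.absorbance):
            raise InvalidArgumentError("times and absorbance differ in length")
        if len(self.times) < 5:
            raise InvalidArgumentError("need >= 5 points for slope fitting")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")


@dataclass(frozen=True)
class Calibration:
    slope: float  # absorbance per mol phosphate
    intercept: float
    r_squared: float


def fit_calibration(
    standards: Sequence[tuple[float, float]], force: bool = False
) -> Calibration:
    """Ordinary least-squares phosphate calibration line.

    ``standards`` are (phosphate amount in mol, absorbance) pairs; at
    least two distinct amounts are needed.  A fit with r^2 < 0.98 is
    refused unless ``force`` — a bad standard curve invalidates every
    downstream rate.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 calibration standards")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 2:
        raise InvalidArgumentError("standards need >= 2 distinct phosphate amounts")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 < 0.98 and not force:
        raise InvalidArgumentError(
            f"calibration r^2 = {r2:.4f} < 0.98; pass force=True to accept"
        )
    return Calibration(float(res.slope), float(res.intercept), r2)


def endpoint_rate(
    absorbance: float,
    blanks: Sequence[float],
    calibration: Calibration,
    incubation_time_min: float,
) -> tuple[float, bool]:
    """(rate in mol product/min, detectable flag) for an endpoint reading.

    rate = max(0, (A - blank_mean - intercept) / slope) / time; a signal
    is detectable when it exceeds blank mean + 3 SD of the blanks.
    """
    if incubation_time_min <= 0:
        raise InvalidArgumentError("incubation time must be positive")
    if calibration.slope <= 0:
        raise InvalidArgumentError("calibration slope must be positive")
    blanks = np.asarray(blanks, dtype=float)
    blank_mean = float(blanks.mean())
    blank_sd = float(blanks.std(ddof=1)) if len(blanks) > 1 else 0.0
    rate = max(
        0.0, (absorbance - blank_mean - calibration.intercept) / calibration.slope
    ) / incubation_time_min
    detectable = absorbance > blank_mean + 3.0 * blank_sd
    return rate, detectable


def timecourse_rate(
    tc: AssayTimeCourse,
    conversion_factor: float,
    r2_min: float = 0.99,
    min_points: int = 5,
) -> tuple[float, bool]:
    """(rate, low_linearity_warning) from the linear phase of a time course.

    The rate is the slope (absorbance/min) of the longest initial window
    whose linear fit reaches r^2 >= r2_min (at least ``min_points``
    points), times ``conversion_factor`` (mol per absorbance unit).  A
    flat course has r^2 undefined in the limit; slopes indistinguishable
    from zero are handled by treating an (essentially) constant window as
    perfectly linear.  If no window qualifies, the full course is fitted
    and a low-linearity warning is raised.
    """
    t_min = tc.times / 60.0
    y = tc.absorbance
    best_end = None
    for end in range(min_points, len(t_min) + 1):
        res = stats.linregress(t_min[:end], y[:end])
        ss_tot = float(np.var(y[:end]))
        # a constant signal is trivially linear (zero slope)
        r2 = 1.0 if ss_tot < 1e-30 else float(res.rvalue**2)
        if r2 >= r2_min:
            best_end = end
    if best_end is None:
        res = stats.linregress(t_min, y)
        return float(res.slope) * conversion_factor, True
    res = stats.linregress(t_min[:best_end], y[:best_end])
    slope = 0.0 if np.var(y[:best_end]) < 1e-30 else float(res.slope)
    return slope * conversion_factor, False


def oa_attribution(
    rate_untreated: float,
    rate_treated: float,
    enzyme_conc: float,
    inhibitor_conc: float,
    f_threshold: float = 0.9,
    untreated_detectable: bool = True,
) -> tuple[str, float]:
    """Attribute measured activity to the target enzyme or a contaminant.

    f is the inhibited fraction, clip(1 - treated/untreated, 0, 1)
    (0 when the untreated rate itself is below detectability).  Activity
    is ``contaminant_attributed`` when f >= f_threshold *and* the target
    enzyme is in molar excess over the inhibitor — a sub-stoichiometric
    inhibitor cannot silence the target itself, so near-total inhibition
    implicates a trace contaminant.  ``target_attributed`` when
    f < 1 - f_threshold; anything in between is ``indeterminate``.
    """
    if rate_untreated < 0 or rate_treated < 0:
        raise InvalidArgumentError("rates must be nonnegative")
    if rate_untreated == 0 or not untreated_detectable:
        f = 0.0
    else:
        f = float(np.clip(1.0 - rate_treated / rate_untreated, 0.0, 1.0))
    if f >= f_threshold and enzyme_conc > inhibitor_conc:
        return "contaminant_attributed", f
    if f < 1.0 - f_threshold:
        return "target_attributed", f
    return "indeterminate", f


def alkylation_accessibility(
    table: pd.DataFrame,
    pseudocount: float = 1.0,
    t_buried: float = 2.0,
    t_exposed: float = -1.0,
) -> pd.DataFrame:
    """Per-cysteine solvent-accessibility call from MMTS:IAA intensities.

    ``table`` columns: residue, peptide, intensity_IAA, intensity_MMTS.
    The score is log2((I_MMTS + pc) / (I_IAA + pc)); a high ratio means
    the residue escaped native-state IAA labeling (buried or otherwise
    protected), a low ratio means it was freely labeled (exposed).
    Within-row ratios cancel peptide-specific ionization efficiency.
    """
    if pseudocount <= 0:
        raise InvalidArgumentError("pseudocount must be positive")
    if (table[["intensity_IAA", "intensity_MMTS"]] < 0).any().any():
        raise InvalidArgumentError("intensities must be nonnegative")
    out = table.copy()
    out["log2_ratio"] = np.log2(
        (out["intensity_MMTS"] + pseudocount) / (out["intensity_IAA"] + pseudocount)
    )
    out["call"] = np.select(
        [out["log2_ratio"] >= t_buried, out["log2_ratio"] <= t_exposed],
        ["buried", "exposed"],
        default="intermediate",
    )
    return out
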