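import numpy as np
import pandas as pd
import pytest

from pseudolock.biochem import (
    AssayTimeCourse,
    Calibration,
    alkylation_accessibility,
    endpoint_rate,
    fit_calibration,
    oa_attribution,
    timecourse_rate,
)
from pseudolock.errors import InvalidArgumentError
from pseudolock.simulate import sim_assay


class TestCalibration:
    def test_noiseless_line_recovered_exactly(self):
        standards = [(x, 2.0 * x + 0.01) for x in (0.0, 1.0, 2.0, 3.0)]
        calib = fit_calibration(standards)
        assert calib.slope == pytest.approx(2.0)
        assert calib.intercept == pytest.approx(0.01)
        assert calib.r_squared == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        calib = fit_calibration([(0.0, 0.1), (2.0, 4.1)])
        assert calib.slope == pytest.approx(2.0)
        assert calib.r_squared == pytest.approx(1.0)

    def test_poor_fit_refused_unless_forced(self):
        standards = [(0, 0.0), (1, 5.0), (2, 0.5), (3, 9.0)]
        with pytest.raises(InvalidArgumentError):
            fit_calibration(standards)
        assert fit_calibration(standards, force=True).r_squared < 0.98

    def test_degenerate_x_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_calibration([(1.0, 0.1), (1.0, 0.2), (1.0, 0.3)])

    @pytest.mark.parametrize("seed", range(10))
    def test_slope_recovered_within_two_percent_from_noisy_standards(self, seed):
        sim = sim_assay([1e-11], 5e8, 0.01, 0.0, False, noise_sd=0.002, seed=seed)
        calib = fit_calibration(
            list(zip(sim.standards["phosphate_mol"], sim.standards["absorbance"]))
        )
        assert calib.slope == pytest.approx(5e8, rel=0.02)


class TestEndpointRate:
    def test_blank_level_signal_is_zero_and_undetectable(self):
        calib = Calibration(2.0, 0.0, 1.0)
        blanks = [0.1, 0.11, 0.09, 0.1]
        rate, detectable = endpoint_rate(0.1, blanks, calib, 60.0)
        assert rate == 0.0 and not detectable

    def test_noiseless_simulation_inverted_exactly(self):
        r = 3e-11
        sim = sim_assay([r], 5e8, 0.01, 0.0, False, noise_sd=0.0, seed=0)
        calib = fit_calibration(
            list(zip(sim.standards["phosphate_mol"], sim.standards["absorbance"]))
        )
        a = sim.endpoints.query("condition == 'untreated'")["absorbance"].iloc[0]
        rate, detectable = endpoint_rate(a, sim.blanks, calib, 60.0)
        assert rate == pytest.approx(r, rel=1e-9)
        assert detectable

    def test_zero_rate_with_noise_rarely_detectable(self):
        false_calls = 0
        n = 1000
        calib = Calibration(5e8, 0.0, 1.0)
        rng = np.random.default_rng(12)
        for _ in range(n):
            blanks = 0.05 + 0.002 * rng.standard_normal(6)
            a = 0.05 + 0.002 * rng.standard_normal()
            _, det = endpoint_rate(a, blanks, calib, 60.0)
            false_calls += det
        assert false_calls / n <= 0.01  # the 3-sigma rule holds

    def test_nonpositive_time_rejected(self):
        with pytest.raises(InvalidArgumentError):
            endpoint_rate(0.5, [0.1], Calibration(1.0, 0.0, 1.0), 0.0)


class TestTimecourseRate:
    def test_perfectly_linear_course(self):
        t = np.arange(0, 600, 30.0)
        tc = AssayTimeCourse(times=t, absorbance=0.1 + 0.004 * (t / 60.0))
        rate, warn = timecourse_rate(tc, conversion_factor=2.0)
        assert rate == pytest.approx(0.008)
        assert not warn

    def test_flat_course_zero_rate(self):
        t = np.arange(0, 600, 30.0)
        tc = AssayTimeCourse(times=t, absorbance=np.full(len(t), 0.2))
        rate, warn = timecourse_rate(tc, conversion_factor=1.0)
        assert rate == 0.0 and not warn

    def test_plateau_excluded_from_initial_window(self):
        # the r^2-qualified prefix stops shortly after the kink; the few
        # admitted plateau points bias the slope down by ~5%, the known
        # cost of the threshold rule on a hard-kink course
        t = np.arange(0, 3600, 30.0)
        t_min = t / 60.0
        linear = 0.01 * t_min
        saturating = np.minimum(linear, 0.01 * 20.0)  # kink at 20 min
        tc = AssayTimeCourse(times=t, absorbance=0.05 + saturating)
        rate, warn = timecourse_rate(tc, conversion_factor=1.0)
        assert not warn
        assert 0.0 < 0.01 - rate <= 0.065 * 0.01
        assert rate == pytest.approx(0.009482, rel=1e-3)  # frozen derived value

    def test_nonlinear_course_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 300, 30.0)
        y = rng.random(len(t))  # no linear 5-point prefix at r2 >= 0.99
        tc = AssayTimeCourse(times=t, absorbance=y)
        _, warn = timecourse_rate(tc, conversion_factor=1.0)
        assert warn

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            AssayTimeCourse(times=[0, 30, 60], absorbance=[0, 0.1, 0.2])


class TestOaAttribution:
    def test_total_inhibition_with_molar_excess_is_contaminant(self):
        # inhibitor-sensitive activity in a prep with the enzyme at 100 nM
        # vs 12.5 nM inhibitor: the enzyme cannot be the source
        verdict, f = oa_attribution(2e-11, 0.0, 100e-9, 12.5e-9)
        assert verdict == "contaminant_attributed"
        assert f == pytest.approx(1.0)

    def test_uninhibited_activity_is_target(self):
        verdict, f = oa_attribution(2e-11, 2e-11, 100e-9, 12.5e-9)
        assert verdict == "target_attributed" and f == 0.0

    def test_partial_inhibition_is_indeterminate(self):
        verdict, _ = oa_attribution(2e-11, 1e-11, 100e-9, 12.5e-9)
        assert verdict == "indeterminate"

    def test_undetectable_untreated_rate_gives_zero_fraction(self):
        verdict, f = oa_attribution(
            1e-12, 0.0, 100e-9, 12.5e-9, untreated_detectable=False
        )
        assert f == 0.0 and verdict == "target_attributed"

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.3, 100.0])
    def test_scale_invariance(self, c):
        base = oa_attribution(3e-11, 1e-12, 100e-9, 12.5e-9)
        scaled = oa_attribution(c * 3e-11, c * 1e-12, 100e-9, 12.5e-9)
        assert base[0] == scaled[0]
        assert base[1] == pytest.approx(scaled[1])

    def test_simulated_contaminated_prep_round_trip(self):
        for seed in range(10):
            sim = sim_assay([0.0], 5e8, 0.01, 2e-11, True, noise_sd=0.002, seed=seed)
            calib = fit_calibration(
                list(zip(sim.standards["phosphate_mol"], sim.standards["absorbance"]))
            )
            ep = sim.endpoints.set_index("condition")["absorbance"]
            r_un, det = endpoint_rate(ep["untreated"], sim.blanks, calib, 60.0)
            r_tr, _ = endpoint_rate(ep["inhibitor"], sim.blanks, calib, 60.0)
            verdict, _ = oa_attribution(
                r_un, r_tr, 100e-9, 12.5e-9, untreated_detectable=det
            )
            assert verdict == "contaminant_attributed"


class TestAlkylation:
    def table(self, i_iaa, i_mmts):
        return pd.DataFrame(
            {
                "residue": [1],
                "peptide": ["p1"],
                "intensity_IAA": [i_iaa],
                "intensity_MMTS": [i_mmts],
            }
        )

    def test_mmts_dominant_is_buried(self):
        out = alkylation_accessibility(self.table(1e4, 1e6))
        assert out["call"].iloc[0] == "buried"

    def test_iaa_dominant_is_exposed(self):
        out = alkylation_accessibility(self.table(1e6, 1e4))
        assert out["call"].iloc[0] == "exposed"

    def test_balanced_is_intermediate(self):
        out = alkylation_accessibility(self.table(1e5, 1e5))
        assert out["call"].iloc[0] == "intermediate"

    @pytest.mark.parametrize("c", [10.0, 100.0])
    def test_intensity_scale_invariance(self, c):
        base = alkylation_accessibility(self.table(1e6, 3e7))
        scaled = alkylation_accessibility(self.table(c * 1e6, c * 3e7))
        assert scaled["log2_ratio"].iloc[0] == pytest.approx(
            base["log2_ratio"].iloc[0], rel=1e-6
        )
        assert scaled["call"].iloc[0] == base["call"].iloc[0]

    def test_pseudocount_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            alkylation_accessibility(self.table(1, 1), pseudocount=0.0)
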