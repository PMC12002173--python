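"""Somatic mutation-burden comparison of gene classes.

Reproduces the COSMIC-style comparison by which tumor-suppressor genes
(high truncating fraction, copy-number-loss skew), oncogenes (missense
hotspots, copy-number-gain skew) and neutral genes (olfactory-receptor-
like background rates) are distinguished.  Rates are per-gene totals
normalized by protein length (substitutions per 1,000 amino acids),
matching aggregated COSMIC counts; hotspots are formalized as codons
whose recurrent count is binomially improbable under a uniform
positional model, Benjamini-Hochberg corrected within the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import false_discovery_control

from .errors import InvalidArgumentError, NotFoundError

__all__ = [
    "CONSEQUENCES",
    "TRUNCATING",
    "MutationCatalog",
    "Hotspot",
    "GeneBurden",
    "burden_rates",
    "detect_hotspots",
    "cnv_skew",
    "classify_gene",
    "ClassThresholds",
]

CONSEQUENCES = frozenset({"synonymous", "missense", "nonsense", "frameshift"})
#: consequences counted as truncating / loss-of-function
TRUNCATING = frozenset({"nonsense", "frameshift"})
NONSYNONYMOUS = frozenset({"missense", "nonsense", "frameshift"})
CNV_STATES = frozenset({"loss", "neutral", "gain"})


class MutationCatalog:
    """Per-sample somatic substitution records with protein coordinates.

    ``records``: DataFrame with columns gene, position (1-based codon),
    consequence, sample.  ``gene_lengths``: gene -> protein length (aa).
    """

    def __init__(self, records: pd.DataFrame, gene_lengths: Mapping[str, int]) -> None:
        required = {"gene", "position", "consequence", "sample"}
        missing = required - set(records.columns)
        if missing:
            raise InvalidArgumentError(f"catalog missing columns {sorted(missing)}")
        bad = set(records["consequence"]) - CONSEQUENCES
        if bad:
            raise InvalidArgumentError(f"unknown consequence values {sorted(bad)}")
        self.records = records.reset_index(drop=True)
        self.gene_lengths = dict(gene_lengths)
        for gene, grp in self.records.groupby("gene"):
            length = self.gene_lengths.get(gene)
            if length is None:
                raise NotFoundError(f"no length for gene {gene!r}")
            pos = grp["position"]
            if (pos < 1).any() or (pos > length).any():
                raise InvalidArgumentError(f"position outside [1, {length}] for {gene!r}")

    @classmethod
    def read_tsv(cls, records_path, lengths_path) -> "MutationCatalog":
        rec = pd.read_csv(records_path, sep="\t")
        lens = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0].to_dict()
        return cls(rec, lens)

    def genes(self) -> list[str]:
        return sorted(self.gene_lengths)


@dataclass(frozen=True)
class Hotspot:
    codon: int
    count: int
    q_value: float


@dataclass
class GeneBurden:
    gene: str
    syn_rate: float  # substitutions per 1,000 aa
    nonsyn_rate: float
    truncating_fraction: float
    hotspots: list[Hotspot] = field(default_factory=list)
    cnl_freq: float = 0.0
    cng_freq: float = 0.0
    skew: float = 0.0
    classification: str = "neutral_like"
    conflict: bool = False


def burden_rates(catalog: MutationCatalog) -> pd.DataFrame:
    """Synonymous / nonsynonymous substitution rates per 1,000 aa.

    rate = count * 1000 / length_aa; nonsynonymous pools missense,
    nonsense and frameshift.  Every gene with a known length is reported,
    including genes with zero records.
    """
    rows = []
    rec = catalog.records
    for gene in catalog.genes():
        length = catalog.gene_lengths[gene]
        grp = rec[rec["gene"] == gene]
        syn = int((grp["consequence"] == "synonymous").sum())
        nonsyn = int(grp["consequence"].isin(NONSYNONYMOUS).sum())
        trunc = int(grp["consequence"].isin(TRUNCATING).sum())
        rows.append(
            dict(
                gene=gene,
                length_aa=length,
                syn_count=syn,
                nonsyn_count=nonsyn,
                syn_rate=syn * 1000.0 / length,
                nonsyn_rate=nonsyn * 1000.0 / length,
                truncating_fraction=trunc / nonsyn if nonsyn else 0.0,
            )
        )
    return pd.DataFrame(rows).set_index("gene")


def detect_hotspots(
    catalog: MutationCatalog, gene: str, alpha: float = 0.05, min_count: int = 3
) -> list[Hotspot]:
    """Codons with binomially improbable recurrent nonsynonymous counts.

    For a codon carrying k of the gene's m nonsynonymous records over L
    codons, p = P[Binomial(m, 1/L) >= k]; Benjamini-Hochberg across all
    L codons of the gene (codons without records contribute p = 1, so the
    correction accounts for the codons implicitly scanned, not just the
    ones that happened to collect hits); a hotspot needs q <= alpha and
    k >= min_count.
    """
    if gene not in catalog.gene_lengths:
        raise NotFoundError(f"gene {gene!r} not in catalog")
    rec = catalog.records
    grp = rec[(rec["gene"] == gene) & rec["consequence"].isin(NONSYNONYMOUS)]
    if grp.empty:
        return []
    length = catalog.gene_lengths[gene]
    counts = grp["position"].value_counts().sort_index()
    m = int(counts.sum())
    pvals = stats.binom.sf(counts.to_numpy() - 1, m, 1.0 / length)
    padded = np.concatenate([pvals, np.ones(length - len(pvals))])
    qvals = false_discovery_control(padded)[: len(pvals)]
    out = [
        Hotspot(int(codon), int(k), float(q))
        for codon, k, q in zip(counts.index, counts.to_numpy(), qvals)
        if q <= alpha and k >= min_count
    ]
    return sorted(out, key=lambda h: h.codon)


def cnv_skew(cnv_table: pd.DataFrame) -> tuple[float, float, float]:
    """(cnl_freq, cng_freq, skew) from per-sample copy-number calls.

    ``cnv_table`` has one row per sample with a ``call`` column in
    {loss, neutral, gain}.  skew = (cng - cnl) / (cng + cnl), 0 when no
    events.
    """
    if cnv_table.empty:
        raise InvalidArgumentError("empty CNV table")
    bad = set(cnv_table["call"]) - CNV_STATES
    if bad:
        raise InvalidArgumentError(f"unknown CNV calls {sorted(bad)}")
    n = len(cnv_table)
    cnl = float((cnv_table["call"] == "loss").sum()) / n
    cng = float((cnv_table["call"] == "gain").sum()) / n
    skew = 0.0 if cnl + cng == 0 else (cng - cnl) / (cng + cnl)
    return cnl, cng, skew


@dataclass(frozen=True)
class ClassThresholds:
    t_trunc: float = 0.2  # min truncating fraction for a TSG-like call
    t_skew: float = 0.3  # min |CNV skew| supporting either call


def classify_gene(
    burden_row: Mapping,
    hotspots: list[Hotspot],
    cnv: tuple[float, float, float],
    thresholds: ClassThresholds = ClassThresholds(),
) -> tuple[str, bool]:
    """Gene-class call from burden, hotspot and CNV evidence.

    tsg_like: truncating fraction >= t_trunc and CNV skew <= -t_skew.
    oncogene_like: >= 1 hotspot and skew >= +t_skew.  When both rules
    fire, the oncogene rule wins and the conflict is flagged.  Everything
    else (including a mutation-free gene) is neutral_like.
    """
    _, _, skew = cnv
    trunc = float(burden_row["truncating_fraction"])
    tsg = trunc >= thresholds.t_trunc and skew <= -thresholds.t_skew
    onc = len(hotspots) >= 1 and skew >= thresholds.t_skew
    if onc:
        return "oncogene_like", tsg
    if tsg:
        return "tsg_like", False
    return "neutral_like", False


def gene_burden(
    catalog: MutationCatalog,
    cnv_tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    thresholds: ClassThresholds = ClassThresholds(),
) -> list[GeneBurden]:
    """Full per-gene burden report: rates, hotspots, CNV skew and class."""
    rates = burden_rates(catalog)
    out = []
    for gene in catalog.genes():
        row = rates.loc[gene]
        hs = detect_hotspots(catalog, gene, alpha=alpha) if row["nonsyn_count"] else []
        if gene in cnv_tables and not cnv_tables[gene].empty:
            cnv = cnv_skew(cnv_tables[gene])
        else:
            cnv = (0.0, 0.0, 0.0)
        cls, conflict = classify_gene(row, hs, cnv, thresholds)
        out.append(
            GeneBurden(
                gene=gene,
                syn_rate=float(row["syn_rate"]),
                nonsyn_rate=float(row["nonsyn_rate"]),
                truncating_fraction=float(row["truncating_fraction"]),
                hotspots=hs,
                cnl_freq=cnv[0],
                cng_freq=cnv[1],
                skew=cnv[2],
                classification=cls,
                conflict=conflict,
            )
        )
    return out
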