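"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here, with the truth
recorded in a :class:`SimTruth` so downstream inference can be scored by
parameter recovery:

* pure-birth trees and single-gain/irreversible-loss (Dollo) binary
  characters;
* presence/absence matrices with planted coevolving genes;
* alignments in which a chosen clade has degraded catalytic motifs;
* COSMIC-like mutation catalogs with class-specific signatures
  (truncating + copy-number-loss for tumor suppressors, hotspots +
  copy-number-gain for oncogenes, uniform background for neutral genes);
* two-label cysteine-alkylation intensity tables with buried/exposed
  classes;
* phosphate-calibration standards and absorbance time courses with an
  okadaic-acid-sensitive contaminant fraction.

All generators are pure functions of their arguments including the seed:
identical calls give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .active_site import CatalyticSiteModel, AMINO_ACIDS
from .biochem import AssayTimeCourse
from .dollo import BinaryCharacterMatrix
from .errors import InvalidArgumentError, NotFoundError
from .phylo import Phylogeny

__all__ = [
    "SimTruth",
    "GeneSpec",
    "sim_tree",
    "sim_dollo_character",
    "sim_profile_matrix",
    "sim_catalytic_msa",
    "sim_mutation_catalog",
    "sim_alkylation_table",
    "sim_assay",
    "AssaySim",
]


@dataclass
class SimTruth:
    """Ground-truth container for parameter-recovery tests.

    Only the fields relevant to the generator that produced it are set.
    """

    character_events: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    coevolving_gene_ids: list[str] = field(default_factory=list)
    sequence_classes: dict[str, str] = field(default_factory=dict)
    gene_specs: dict[str, dict] = field(default_factory=dict)
    cysteine_classes: dict[int, str] = field(default_factory=dict)
    assay_truth: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# trees and Dollo characters
# ---------------------------------------------------------------------------

def sim_tree(n_tips: int, seed: int) -> Phylogeny:
    """Rooted binary tree under a pure-birth (Yule) process.

    Tips are labeled ``t1..tn`` and internal nodes ``nK`` in preorder;
    branch lengths are exponential waiting times and strictly positive.
    """
    if n_tips < 2:
        raise InvalidArgumentError("a rooted binary tree needs >= 2 tips")
    rng = np.random.default_rng(seed)
    # grow topology: split a uniformly chosen active lineage until n_tips
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"x{counter[0]}"

    root = fresh()
    parent: dict[str, str] = {}
    active = []
    for _ in range(2):
        c = fresh()
        parent[c] = root
        active.append(c)
    while len(active) < n_tips:
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        for _ in range(2):
            c = fresh()
            parent[c] = node
            active.append(c)
    blens = {child: float(rng.exponential(1.0) + 1e-3) for child in parent}
    tmp = Phylogeny(parent, root, blens)

    # relabel deterministically: internal nodes nK by preorder index, tips t1..tn
    rename: dict[str, str] = {}
    tip_i = 0
    for idx, node in enumerate(tmp.preorder()):
        if tmp.is_tip(node):
            tip_i += 1
            rename[node] = f"t{tip_i}"
        else:
            rename[node] = f"n{idx}"
    parent2 = {rename[c]: rename[p] for c, p in parent.items()}
    blens2 = {rename[c]: l for c, l in blens.items()}
    return Phylogeny(parent2, rename[root], blens2)


def sim_dollo_character(
    tree: Phylogeny,
    gain_edge: str,
    loss_rate: float,
    seed: int,
    missing_fraction: float = 0.0,
) -> tuple[dict[str, int | None], tuple[str, list[str]]]:
    """Single-gain / irreversible-loss character evolution.

    State 1 arises on ``gain_edge`` (identified by its child node) and
    propagates to descendants; on each edge below, an *active* lineage
    loses the character with probability ``loss_rate`` and stays lost.
    Loss draws are made in preorder over the gain clade, one uniform
    variate per active edge, which fixes the seeded realization exactly.
    Tips outside the gain clade are 0.  With ``missing_fraction`` > 0,
    each tip is independently masked to missing afterward.

    Returns (tip_states, (gain_edge, realized loss edges)).
    """
    if not tree.has_edge(gain_edge):
        raise NotFoundError(f"edge {gain_edge!r} not in tree")
    if not 0 <= loss_rate < 1:
        raise InvalidArgumentError("loss_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    state: dict[str, int] = {}
    losses: list[str] = []
    clade = set(tree.subtree_nodes(gain_edge))
    for node in tree.preorder():
        if node == gain_edge:
            state[node] = 1
        elif node in clade:
            par_state = state[tree.parent(node)]
            if par_state == 0:
                state[node] = 0
            elif rng.random() < loss_rate:
                state[node] = 0
                losses.append(node)
            else:
                state[node] = 1
        else:
            state[node] = 0
    tip_states: dict[str, int | None] = {t: state[t] for t in tree.tips}
    if missing_fraction > 0:
        for t in tree.tips:
            if rng.random() < missing_fraction:
                tip_states[t] = None
    return tip_states, (gain_edge, losses)


def _nonconstant_dollo(
    tree: Phylogeny, gain_edge: str, loss_rate: float, rng: np.random.Generator
) -> tuple[dict[str, int], tuple[str, list[str]]]:
    """Redraw until the character varies across tips (a profiling screen
    needs variable profiles; an all-present or all-absent query is
    uninformative by construction)."""
    for _ in range(1000):
        states, events = sim_dollo_character(
            tree, gain_edge, loss_rate, int(rng.integers(2**31))
        )
        vals = set(states.values())
        if vals == {0, 1}:
            return states, events
    raise InvalidArgumentError(
        "could not draw a non-constant character; loss_rate too extreme"
    )


def sim_profile_matrix(
    tree: Phylogeny,
    n_genes: int,
    n_coevolving: int,
    flip_noise: float,
    seed: int,
    loss_rate: float = 0.1,
    query_name: str = "query",
) -> tuple[BinaryCharacterMatrix, SimTruth]:
    """Presence/absence matrix with planted coevolving genes.

    A query character is evolved from the root under Dollo dynamics;
    each of the first ``n_coevolving`` genes copies the query's tip
    profile and then flips each tip state independently with probability
    ``flip_noise``; the remaining genes are independent Dollo characters
    (also gained at the root, lost at ``loss_rate`` per branch).
    """
    if n_coevolving > n_genes:
        raise InvalidArgumentError("n_coevolving must be <= n_genes")
    rng = np.random.default_rng(seed)
    tips = list(tree.tips)
    truth = SimTruth()

    qstates, qevents = _nonconstant_dollo(tree, tree.root, loss_rate, rng)
    truth.character_events[query_name] = qevents

    columns: dict[str, dict[str, int | None]] = {query_name: dict(qstates)}
    width = len(str(max(n_genes, 1)))
    for i in range(n_genes):
        name = f"g{i + 1:0{width}d}"
        if i < n_coevolving:
            states = {
                t: (1 - qstates[t]) if rng.random() < flip_noise else qstates[t]
                for t in tips
            }
            truth.coevolving_gene_ids.append(name)
            truth.character_events[name] = qevents
        else:
            states, events = _nonconstant_dollo(tree, tree.root, loss_rate, rng)
            truth.character_events[name] = events
        columns[name] = dict(states)
    matrix = BinaryCharacterMatrix.from_states(columns, tips)
    return matrix, truth


# ---------------------------------------------------------------------------
# catalytic-site alignments
# ---------------------------------------------------------------------------

def sim_catalytic_msa(
    tree: Phylogeny,
    site_model: CatalyticSiteModel,
    pseudo_clade: str,
    seed: int,
    p_conserve: float = 0.8,
    p_extra_degrade: float = 0.3,
) -> tuple[dict[str, str], SimTruth]:
    """Ungapped alignment with clade-restricted catalytic-motif decay.

    One sequence per tip plus the model's reference row.  Sequences
    descending from ``pseudo_clade`` carry at least one disallowed
    residue at a required M1/M2 position (each further required position
    degrades with probability ``p_extra_degrade``); all other sequences
    carry allowed residues at every required position.  Non-site columns
    follow a random column consensus kept with probability
    ``p_conserve``.  The disallowed substitution palette is all 20 amino
    acids minus the site's allowed set, so cysteine can (and does)
    appear at degraded M2 aspartate positions.
    """
    if pseudo_clade not in tree:
        raise NotFoundError(f"node {pseudo_clade!r} not in tree")
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    positions = [s.position for s in site_model.sites]
    length = max(positions) + 10
    site_at = {s.position: s for s in site_model.sites}
    required = [s for s in site_model.sites if s.required and s.role in ("M1", "M2")]

    consensus = [aas[int(rng.integers(20))] for _ in range(length)]
    pseudo_tips = set(tree.subtree_tips(pseudo_clade))
    if tree.is_tip(pseudo_clade):
        pseudo_tips.add(pseudo_clade)

    truth = SimTruth()
    aln: dict[str, str] = {}

    def background(col: int) -> str:
        if rng.random() < p_conserve:
            return consensus[col]
        return aas[int(rng.integers(20))]

    # reference row: canonical allowed residue at every site
    ref = []
    for col in range(length):
        pos = col + 1
        if pos in site_at:
            ref.append(sorted(site_at[pos].allowed)[0])
        else:
            ref.append(consensus[col])
    aln[site_model.reference_id] = "".join(ref)

    for tip in tree.tips:
        is_pseudo = tip in pseudo_tips
        if is_pseudo:
            broken = {
                s.position for s in required if rng.random() < p_extra_degrade
            }
            if not broken:
                broken = {required[int(rng.integers(len(required)))].position}
        else:
            broken = set()
        seq = []
        for col in range(length):
            pos = col + 1
            site = site_at.get(pos)
            if site is None:
                seq.append(background(col))
            elif pos in broken:
                palette = [a for a in aas if a not in site.allowed]
                seq.append(palette[int(rng.integers(len(palette)))])
            elif site.required or site.role in ("M1", "M2", "M3"):
                allowed = sorted(site.allowed)
                seq.append(allowed[int(rng.integers(len(allowed)))])
            else:
                seq.append(background(col))
        aln[tip] = "".join(seq)
        truth.sequence_classes[tip] = "pseudo" if is_pseudo else "active"
    return aln, truth


# ---------------------------------------------------------------------------
# mutation catalogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """Generative spec for one gene's somatic-mutation signature.

    Rates are substitutions per 1,000 aa aggregated over the catalog
    (COSMIC-style totals); ``hotspot_fraction`` is the fraction of
    missense events concentrated on the hotspot codons; CNV
    probabilities are per sample.
    """

    name: str
    gene_class: str  # tsg | oncogene | neutral
    length_aa: int
    # catalog-wide totals; COSMIC-aggregated counts are large even for
    # passenger genes, these defaults are a scaled-down emulation
    syn_rate: float = 50.0
    nonsyn_rate: float = 150.0
    hotspot_codons: tuple[int, ...] = ()
    hotspot_fraction: float = 0.0
    truncating_fraction: float = 0.05
    cnl_prob: float = 0.02
    cng_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.gene_class not in ("tsg", "oncogene", "neutral"):
            raise InvalidArgumentError(f"unknown gene class {self.gene_class!r}")
        if self.length_aa < 50:
            raise InvalidArgumentError("gene length must be >= 50 aa")
        if min(self.syn_rate, self.nonsyn_rate) < 0:
            raise InvalidArgumentError("rates must be nonnegative")
        for c in self.hotspot_codons:
            if not 1 <= c <= self.length_aa:
                raise InvalidArgumentError(f"hotspot codon {c} outside [1, {self.length_aa}]")
        for p in (self.hotspot_fraction, self.truncating_fraction, self.cnl_prob, self.cng_prob):
            if not 0 <= p <= 1:
                raise InvalidArgumentError("probabilities must be in [0, 1]")

    @staticmethod
    def neutral(name: str, length_aa: int = 400) -> "GeneSpec":
        return GeneSpec(name, "neutral", length_aa)

    @staticmethod
    def tsg(name: str, length_aa: int = 400) -> "GeneSpec":
        return GeneSpec(
            name, "tsg", length_aa,
            truncating_fraction=0.5, cnl_prob=0.3, cng_prob=0.02,
        )

    @staticmethod
    def oncogene(
        name: str, length_aa: int = 400, hotspot_codons: tuple[int, ...] = ()
    ) -> "GeneSpec":
        if not hotspot_codons:
            hotspot_codons = (length_aa // 3,)
        return GeneSpec(
            name, "oncogene", length_aa,
            hotspot_codons=hotspot_codons, hotspot_fraction=0.5,
            cnl_prob=0.02, cng_prob=0.3,
        )


def sim_mutation_catalog(
    gene_specs: Sequence[GeneSpec], n_samples: int, seed: int
):
    """COSMIC-like catalog + per-gene CNV tables + truth.

    Substitution counts are Poisson with mean rate * length / 1000;
    positions are uniform except the planted oncogene hotspots; each
    nonsynonymous event is truncating (nonsense/frameshift, 50/50) with
    the spec's truncating fraction.  CNV calls are drawn per sample.
    """
    from .burden import MutationCatalog

    if n_samples < 1:
        raise InvalidArgumentError("need >= 1 sample")
    rng = np.random.default_rng(seed)
    rows = []
    cnv_tables: dict[str, pd.DataFrame] = {}
    truth = SimTruth()
    samples = [f"s{i + 1}" for i in range(n_samples)]

    for spec in gene_specs:
        truth.gene_specs[spec.name] = asdict(spec)
        L = spec.length_aa
        n_syn = int(rng.poisson(spec.syn_rate * L / 1000.0))
        for _ in range(n_syn):
            rows.append(
                (spec.name, int(rng.integers(1, L + 1)), "synonymous",
                 samples[int(rng.integers(n_samples))])
            )
        n_nonsyn = int(rng.poisson(spec.nonsyn_rate * L / 1000.0))
        for _ in range(n_nonsyn):
            sample = samples[int(rng.integers(n_samples))]
            if rng.random() < spec.truncating_fraction:
                cons = "nonsense" if rng.random() < 0.5 else "frameshift"
                pos = int(rng.integers(1, L + 1))
            elif spec.hotspot_codons and rng.random() < spec.hotspot_fraction:
                cons = "missense"
                pos = int(spec.hotspot_codons[int(rng.integers(len(spec.hotspot_codons)))])
            else:
                cons = "missense"
                pos = int(rng.integers(1, L + 1))
            rows.append((spec.name, pos, cons, sample))

        u = rng.random(n_samples)
        calls = np.where(
            u < spec.cnl_prob, "loss",
            np.where(u < spec.cnl_prob + spec.cng_prob, "gain", "neutral"),
        )
        cnv_tables[spec.name] = pd.DataFrame({"sample": samples, "call": calls})

    records = pd.DataFrame(rows, columns=["gene", "position", "consequence", "sample"])
    catalog = MutationCatalog(records, {s.name: s.length_aa for s in gene_specs})
    return catalog, cnv_tables, truth


# ---------------------------------------------------------------------------
# alkylation tables
# ---------------------------------------------------------------------------

def sim_alkylation_table(
    n_buried: int,
    n_exposed: int,
    separation: float,
    seed: int,
    sdlog2: float = 0.3,
    base_log10_intensity: float = 6.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-label cysteine intensity table with buried/exposed classes.

    Buried cysteines are MMTS-dominant (protected from native IAA
    labeling), exposed ones IAA-dominant; the expected log2(MMTS/IAA)
    ratios of the two classes are centered on the classifier thresholds'
    midpoint and separated by ``separation``.  Per-label intensities get
    independent log-normal noise (sd ``sdlog2`` in log2 units).
    """
    if separation <= 0:
        raise InvalidArgumentError("separation must be positive")
    rng = np.random.default_rng(seed)
    center = 0.5  # midpoint of the default buried/exposed thresholds (2, -1)
    mus = [center + separation / 2.0] * n_buried + [center - separation / 2.0] * n_exposed
    classes = ["buried"] * n_buried + ["exposed"] * n_exposed
    rows = []
    truth = SimTruth()
    for i, (mu, cls) in enumerate(zip(mus, classes)):
        residue = 10 * (i + 1)  # synthetic residue numbering
        base = 10.0 ** (base_log10_intensity + 0.5 * rng.standard_normal())
        i_mmts = base * 2.0 ** (mu / 2.0 + sdlog2 * rng.standard_normal())
        i_iaa = base * 2.0 ** (-mu / 2.0 + sdlog2 * rng.standard_normal())
        rows.append((residue, f"pep{i + 1}", i_iaa, i_mmts))
        truth.cysteine_classes[residue] = cls
    table = pd.DataFrame(
        rows, columns=["residue", "peptide", "intensity_IAA", "intensity_MMTS"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# enzyme assays
# ---------------------------------------------------------------------------

@dataclass
class AssaySim:
    standards: pd.DataFrame  # phosphate_mol, absorbance
    endpoints: pd.DataFrame  # rate_index, condition, absorbance
    blanks: np.ndarray
    courses: list[dict]  # {rate_index, condition, timecourse}
    truth: SimTruth


def sim_assay(
    true_rates: Sequence[float],
    calib_slope: float,
    calib_intercept: float,
    contaminant_rate: float,
    oa_inhibits_contaminant: bool,
    noise_sd: float,
    seed: int,
    incubation_time_min: float = 60.0,
    enzyme_conc: float = 100e-9,
    inhibitor_conc: float = 12.5e-9,
    n_blanks: int = 6,
    baseline: float = 0.05,
) -> AssaySim:
    """Calibration standards plus paired +/- inhibitor assay readouts.

    Standards lie on absorbance = slope * phosphate + intercept (+ noise).
    For each true rate r the untreated signal encodes r + contaminant;
    the inhibitor-treated signal drops the contaminant term iff
    ``oa_inhibits_contaminant`` (the okadaic-acid-sensitive scenario).
    Endpoint absorbances and 30-second kinetic courses over 90 min are
    both produced; at ``noise_sd`` = 0 ``endpoint_rate`` inverts the
    generator exactly.
    """
    if not np.isfinite(calib_slope) or not np.isfinite(calib_intercept):
        raise InvalidArgumentError("calibration parameters must be finite")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)

    amounts = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0]) * 1e-9  # mol phosphate
    std_abs = calib_slope * amounts + calib_intercept + noise_sd * rng.standard_normal(len(amounts))
    standards = pd.DataFrame({"phosphate_mol": amounts, "absorbance": std_abs})

    blanks = baseline + noise_sd * rng.standard_normal(n_blanks)

    endpoint_rows = []
    courses: list[dict] = []
    times = np.arange(0.0, 90.0 * 60.0 + 1, 30.0)  # every 30 s for 90 min
    for i, r in enumerate(true_rates):
        for condition in ("untreated", "inhibitor"):
            total = r + contaminant_rate
            if condition == "inhibitor" and oa_inhibits_contaminant:
                total = r
            a_end = (
                baseline
                + calib_intercept
                + calib_slope * total * incubation_time_min
                + noise_sd * rng.standard_normal()
            )
            endpoint_rows.append((i, condition, a_end))
            course_abs = (
                baseline
                + calib_intercept
                + calib_slope * total * (times / 60.0)
                + noise_sd * rng.standard_normal(len(times))
            )
            courses.append(
                {
                    "rate_index": i,
                    "condition": condition,
                    "timecourse": AssayTimeCourse(
                        times=times,
                        absorbance=course_abs,
                        enzyme_conc=enzyme_conc,
                        inhibitor_conc=0.0 if condition == "untreated" else inhibitor_conc,
                        blanks=blanks,
                    ),
                }
            )

    truth = SimTruth(
        assay_truth=dict(
            calib_slope=calib_slope,
            calib_intercept=calib_intercept,
            true_rates=list(true_rates),
            contaminant_rate=contaminant_rate,
            oa_sensitive=bool(oa_inhibits_contaminant),
            incubation_time_min=incubation_time_min,
            baseline=baseline,
        )
    )
    endpoints = pd.DataFrame(
        endpoint_rows, columns=["rate_index", "condition", "absorbance"]
    )
    return AssaySim(standards, endpoints, blanks, courses, truth)
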