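"""Phylogenomic profiling: ranking genes by presence/absence co-distribution.

Genes that are repeatedly lost together across a species tree are
candidates for a functional association.  The screen correlates each
gene's binary presence/absence profile with a query gene's profile using
the phi coefficient (Pearson correlation of two binary variables,
computed from their 2x2 contingency table) and attaches a
phylogeny-aware permutation p-value: the null keeps the gene's Dollo
gain edge and number of losses, and re-places those losses uniformly at
random on eligible (non-nested, within-gain-clade) edges.  Shuffling
tips i.i.d. instead would ignore phylogenetic autocorrelation and
overstate significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .dollo import BinaryCharacterMatrix, infer_dollo
from .errors import InvalidArgumentError, NotFoundError
from .phylo import Phylogeny

__all__ = [
    "phi_correlation",
    "dollo_permutation_pvalue",
    "rank_coevolving",
]


def _clean_pair(a: Sequence, b: Sequence) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise InvalidArgumentError("profile vectors differ in length")
    if len(a) < 2:
        raise InvalidArgumentError("profiles need length >= 2")
    aa = np.array([np.nan if v is None else float(v) for v in a])
    bb = np.array([np.nan if v is None else float(v) for v in b])
    keep = ~(np.isnan(aa) | np.isnan(bb))
    return aa[keep], bb[keep]


def phi_correlation(a: Sequence, b: Sequence) -> float | None:
    """Phi coefficient of two binary vectors; ``None`` when undefined.

    phi = (n11*n00 - n10*n01) / sqrt(r1*r0*c1*c0) over the pairwise
    complete observations; any zero margin makes phi undefined.
    """
    aa, bb = _clean_pair(a, b)
    n11 = float(np.sum((aa == 1) & (bb == 1)))
    n10 = float(np.sum((aa == 1) & (bb == 0)))
    n01 = float(np.sum((aa == 0) & (bb == 1)))
    n00 = float(np.sum((aa == 0) & (bb == 0)))
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    denom = r1 * r0 * c1 * c0
    if denom == 0:
        return None
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


@dataclass
class _NullSampler:
    """Re-places a fixed number of Dollo losses uniformly on eligible edges."""

    tree: Phylogeny
    gain_node: str
    n_losses: int

    def __post_init__(self) -> None:
        clade = self.tree.subtree_nodes(self.gain_node)
        self.eligible = [n for n in clade if n != self.gain_node]
        self.clade_tips = frozenset(
            t for t in clade if self.tree.is_tip(t)
        )
        # strict descendants of each eligible edge, for nestedness checks
        self.desc: dict[str, frozenset[str]] = {}
        self.tips_below: dict[str, frozenset[str]] = {}
        for e in self.eligible:
            sub = self.tree.subtree_nodes(e)
            self.desc[e] = frozenset(sub) - {e}
            self.tips_below[e] = frozenset(t for t in sub if self.tree.is_tip(t))
        if self.n_losses > len(self.eligible):
            raise InvalidArgumentError("more losses than eligible edges")

    def _non_nested(self, picks: Sequence[str]) -> bool:
        for i, e in enumerate(picks):
            d = self.desc[e]
            for j, f in enumerate(picks):
                if i != j and f in d:
                    return False
        return True

    def sample_lost_tips(self, rng: np.random.Generator) -> frozenset[str]:
        k = self.n_losses
        if k == 0:
            return frozenset()
        idx = np.arange(len(self.eligible))
        for _ in range(10_000):
            picks = [self.eligible[i] for i in rng.choice(idx, size=k, replace=False)]
            if self._non_nested(picks):
                break
        else:  # greedy fallback; only reachable for pathological k
            order = list(rng.permutation(idx))
            picks = []
            for i in order:
                e = self.eligible[i]
                if all(e not in self.desc[f] and f not in self.desc[e] for f in picks):
                    picks.append(e)
                if len(picks) == k:
                    break
        lost: set[str] = set()
        for e in picks:
            lost |= self.tips_below[e]
            if self.tree.is_tip(e):
                lost.add(e)
        return frozenset(lost)


class _CascadeSampler:
    """Redraws losses by the Dollo cascade itself, conditioned on the
    reconstructed loss count.

    The per-branch loss probability is estimated from the observed
    history (losses / edges on which an active lineage was at risk) and
    loss sets are drawn by rejection: run the cascade from the gain
    edge, keep realizations with exactly the observed number of losses.
    Unlike uniform placement over non-nested edge sets — its small-rate
    limit — this matches the generative weighting of loss sets, which
    favors losses that prune large subtrees.
    """

    def __init__(self, tree: Phylogeny, gain_node: str, n_losses: int, loss_edges) -> None:
        from .simulate import sim_dollo_character  # deferred: simulate imports dollo

        self._sim = sim_dollo_character
        self.tree = tree
        self.gain_node = gain_node
        self.n_losses = n_losses
        clade = tree.subtree_nodes(gain_node)
        self.clade_tips = frozenset(t for t in clade if tree.is_tip(t))
        n_edges = len(clade) - 1
        below = sum(len(tree.subtree_nodes(e)) - 1 for e in loss_edges)
        examined = max(n_edges - below, 1)
        self.p_hat = float(np.clip(n_losses / examined, 1e-3, 0.8))

    def sample_lost_tips(self, rng: np.random.Generator) -> frozenset[str] | None:
        for _ in range(1000):
            states, (_, losses) = self._sim(
                self.tree, self.gain_node, self.p_hat, int(rng.integers(2**31))
            )
            if len(losses) == self.n_losses:
                return frozenset(t for t in self.clade_tips if states[t] == 0)
        return None  # conditioning too tight; caller falls back


def dollo_permutation_pvalue(
    tree: Phylogeny,
    query_states: Mapping[str, int | None],
    gene_states: Mapping[str, int | None],
    n_perm: int = 999,
    seed: int = 0,
    null: str = "cascade",
) -> float:
    """One-sided permutation p-value for the query-gene phi correlation.

    The gene's Dollo reconstruction fixes its gain edge and loss count;
    each permutation re-places that many losses within the gain clade,
    rebuilds the implied tip profile (preserving the gene's missing-data
    pattern), and recomputes phi against the query.
    p = (1 + #{phi_null >= phi_obs}) / (1 + n_perm).

    ``null`` selects the loss re-placement distribution: ``"cascade"``
    (default) redraws losses from the Dollo cascade conditioned on the
    loss count, which is calibrated under the generative model;
    ``"uniform"`` places them uniformly over non-nested edge sets, the
    small-loss-rate limit of the cascade (mildly anticonservative at
    realistic loss rates).
    """
    if n_perm < 99:
        raise InvalidArgumentError("n_perm must be >= 99")
    if null not in ("cascade", "uniform"):
        raise InvalidArgumentError(f"unknown null {null!r}")
    recon = infer_dollo(tree, gene_states, "gene")
    if recon.gain_edge is None:
        raise InvalidArgumentError("gene never gained; permutation null undefined")
    tips = list(tree.tips)
    qv = [query_states.get(t) for t in tips]
    gv = [gene_states.get(t) for t in tips]
    phi_obs = phi_correlation(qv, gv)
    if phi_obs is None:
        raise InvalidArgumentError("observed phi undefined (zero margin)")

    uniform = _NullSampler(tree, recon.gain_edge, recon.n_losses)
    sampler = (
        _CascadeSampler(tree, recon.gain_edge, recon.n_losses, recon.loss_edges)
        if null == "cascade"
        else uniform
    )
    missing = {t for t in tips if gene_states.get(t) is None}
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        lost = sampler.sample_lost_tips(rng)
        if lost is None:
            lost = uniform.sample_lost_tips(rng)
        null_profile = [
            None
            if t in missing
            else (1 if (t in sampler.clade_tips and t not in lost) else 0)
            for t in tips
        ]
        phi_null = phi_correlation(qv, null_profile)
        if phi_null is not None and phi_null >= phi_obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def rank_coevolving(
    tree: Phylogeny,
    matrix: BinaryCharacterMatrix,
    query: str,
    n_perm: int = 999,
    seed: int = 0,
    null: str = "cascade",
) -> pd.DataFrame:
    """Rank all non-query genes by phi with the query profile.

    Returns a DataFrame (gene, phi, p, q, rank) ordered by descending
    phi with lexicographic tie-breaking; genes with undefined phi are
    placed last with undefined p.  q-values are Benjamini-Hochberg
    adjusted permutation p-values.
    """
    if query not in matrix.characters:
        raise NotFoundError(f"query {query!r} not in matrix")
    genes = [g for g in matrix.characters if g != query]
    if not genes:
        raise InvalidArgumentError("matrix has no gene other than the query")

    tips = list(tree.tips)
    qstates = matrix.states(query)
    qv = [qstates.get(t) for t in tips]
    seeds = np.random.SeedSequence(seed).spawn(len(genes))

    rows = []
    for gene, ss in zip(genes, seeds):
        gstates = matrix.states(gene)
        gv = [gstates.get(t) for t in tips]
        phi = phi_correlation(qv, gv)
        if phi is None:
            rows.append((gene, np.nan, np.nan))
            continue
        try:
            p = dollo_permutation_pvalue(
                tree, qstates, gstates, n_perm=n_perm,
                seed=int(ss.generate_state(1)[0] % (2**31)), null=null,
            )
        except InvalidArgumentError:
            p = np.nan
        rows.append((gene, phi, p))

    df = pd.DataFrame(rows, columns=["gene", "phi", "p"])
    df["q"] = np.nan
    defined = df["p"].notna()
    if defined.any():
        df.loc[defined, "q"] = false_discovery_control(df.loc[defined, "p"].to_numpy())
    df["_undef"] = df["phi"].isna()
    df = df.sort_values(
        by=["_undef", "phi", "gene"], ascending=[True, False, True]
    ).drop(columns="_undef")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
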