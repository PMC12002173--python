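"""Independent oracles used to check the package's implementations.

These deliberately avoid the code paths they verify: the Dollo oracle
does exhaustive search over all internal-state assignments, the
character re-simulation is a separate recursive transcription of the
documented propagation rule, and the reference-position oracle is a
naive per-character scan.
"""

from __future__ import annotations

import itertools

import numpy as np

from pseudolock.phylo import Phylogeny


def brute_force_min_losses(tree: Phylogeny, tip_states: dict) -> int:
    """Minimum loss count over all single-gain histories, by enumeration.

    Enumerates every 0/1 assignment to internal nodes and missing tips;
    a history is admissible when it has at most one gain (a root state
    of 1 counts as the gain, on the virtual root edge) and matches the
    observed tip states.  Returns the minimal number of 1->0 edges.
    """
    nodes = list(tree.nodes)
    fixed = {t: s for t, s in tip_states.items() if s is not None}
    free = [n for n in nodes if n not in fixed]
    best = None
    for bits in itertools.product((0, 1), repeat=len(free)):
        st = dict(fixed)
        st.update(zip(free, bits))
        gains = 1 if st[tree.root] == 1 else 0
        losses = 0
        for child in nodes:
            par = tree.parent(child)
            if par is None:
                continue
            if st[par] == 0 and st[child] == 1:
                gains += 1
            elif st[par] == 1 and st[child] == 0:
                losses += 1
        if gains <= 1 and (best is None or losses < best):
            best = losses
    return best


def resimulate_dollo(tree: Phylogeny, gain_edge: str, loss_rate: float, seed: int):
    """Recursive re-implementation of the documented character simulation:
    preorder over the gain clade, one uniform draw per active edge."""
    rng = np.random.default_rng(seed)
    states = {t: 0 for t in tree.tips}
    losses = []

    def walk(node: str, active: bool) -> None:
        nonlocal states, losses
        here = active
        if node != gain_edge and active:
            if rng.random() < loss_rate:
                here = False
                losses.append(node)
        elif node != gain_edge:
            here = False
        if tree.is_tip(node):
            states[node] = 1 if here else 0
        for child in tree.children(node):
            walk(child, here)

    walk(gain_edge, True)
    return states, losses


def naive_reference_columns(ref_row: str, positions: list[int]) -> dict[int, int]:
    """Per-character scan mapping ungapped reference positions to columns."""
    out = {}
    k = 0
    for col, ch in enumerate(ref_row, start=1):
        if ch in "-.":
            continue
        k += 1
        if k in positions:
            out[k] = col
    return out


def binomial_tail(k: int, m: int, p: float) -> float:
    """P[Binomial(m, p) >= k] by direct pmf summation."""
    from math import comb

    return sum(comb(m, i) * p**i * (1 - p) ** (m - i) for i in range(k, m + 1))
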