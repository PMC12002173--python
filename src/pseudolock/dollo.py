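"""Dollo parsimony mapping of binary characters onto rooted phylogenies.

Under Dollo parsimony a character (a gene, a domain, an intact active
site) is gained exactly once and can only be lost thereafter.  The unique
most-parsimonious single-gain history places the gain on the edge above
the most recent common ancestor (MRCA) of all taxa carrying the
character, and one loss on the stem edge of every maximal subtree of that
clade containing no carrier.  ``infer_dollo`` computes that history in a
single postorder pass; the loss count it returns is provably minimal
among all single-gain histories (see docs/methods.md for the argument).

Missing tip states are excluded from the MRCA and loss computations and
imputed afterward from the reconstructed state of their parent, so an
unsampled genome never creates a spurious loss event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InvalidArgumentError, NotFoundError
from .phylo import Phylogeny

__all__ = [
    "MISSING",
    "BinaryCharacterMatrix",
    "DolloReconstruction",
    "infer_dollo",
    "count_independent_losses",
    "map_characters",
    "event_table",
]

#: sentinel for an unobserved tip state
MISSING = None


class BinaryCharacterMatrix:
    """Taxa x characters presence/absence matrix with missing-state support.

    Stored as a pandas DataFrame of nullable integers; ``pd.NA`` encodes a
    missing observation.  Row order is taxon order, column order is
    character order.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.astype("Int64")
        bad = frame.stack().dropna().unique()
        if any(v not in (0, 1) for v in bad):
            raise InvalidArgumentError("matrix states must be 0, 1 or missing")
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise InvalidArgumentError("duplicate taxon or character labels")
        self.frame = frame

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    @property
    def characters(self) -> list[str]:
        return list(self.frame.columns)

    def states(self, character: str) -> dict[str, int | None]:
        """Tip-state map for one character; missing entries become ``None``."""
        if character not in self.frame.columns:
            raise NotFoundError(f"character {character!r} not in matrix")
        col = self.frame[character]
        return {t: (None if pd.isna(v) else int(v)) for t, v in col.items()}

    @classmethod
    def from_states(
        cls, columns: Mapping[str, Mapping[str, int | None]], taxa: Sequence[str]
    ) -> "BinaryCharacterMatrix":
        data = {
            ch: [pd.NA if st.get(t) is None else st.get(t) for t in taxa]
            for ch, st in columns.items()
        }
        return cls(pd.DataFrame(data, index=list(taxa)))

    @classmethod
    def read_tsv(cls, path) -> "BinaryCharacterMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["?", "NA", ""])
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", na_rep="?")


@dataclass(frozen=True)
class DolloReconstruction:
    """A single-gain/multiple-loss history for one binary character.

    ``gain_edge`` is the child-node label of the edge on which the 0->1
    transition occurs (the root label denotes the virtual root edge);
    ``None`` means the character was never gained.  ``loss_edges`` hold
    the 1->0 transitions.  ``node_states`` assigns 0/1 to every node,
    with missing tips imputed from their parent.
    """

    character: str
    gain_edge: str | None
    loss_edges: frozenset[str]
    node_states: dict[str, int] = field(repr=False)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def infer_dollo(
    tree: Phylogeny, tip_states: Mapping[str, int | None], character: str = "char"
) -> DolloReconstruction:
    """Most-parsimonious single-gain history consistent with observed tips.

    Parameters
    ----------
    tree
        Rooted phylogeny; polytomies are accepted.
    tip_states
        Map tip label -> 0, 1 or ``None`` (missing).  Every labeled tip
        must exist in the tree and at least one state must be observed.
    """
    observed: dict[str, int] = {}
    for tip, state in tip_states.items():
        if tip not in tree or not tree.is_tip(tip):
            raise NotFoundError(f"tip {tip!r} not in tree")
        if state is MISSING or (isinstance(state, float) and pd.isna(state)):
            continue
        if state not in (0, 1):
            raise InvalidArgumentError(f"state for {tip!r} must be 0, 1 or missing")
        observed[tip] = int(state)
    if not observed:
        raise InvalidArgumentError("all tip states are missing")

    present = [t for t, s in observed.items() if s == 1]
    if not present:
        return DolloReconstruction(
            character, None, frozenset(), {n: 0 for n in tree.nodes}
        )

    gain_node = tree.mrca(present)

    # subtree flags: does the subtree below each node contain an observed 1 / 0?
    has_one: dict[str, bool] = {}
    has_zero: dict[str, bool] = {}
    for node in tree.postorder():
        kids = tree.children(node)
        if not kids:
            has_one[node] = observed.get(node) == 1
            has_zero[node] = observed.get(node) == 0
        else:
            has_one[node] = any(has_one[k] for k in kids)
            has_zero[node] = any(has_zero[k] for k in kids)

    loss_edges: set[str] = set()
    for node in tree.subtree_nodes(gain_node):
        if node == gain_node:
            continue
        par = tree.parent(node)
        if not has_one[node] and has_zero[node] and has_one[par]:
            loss_edges.add(node)

    node_states: dict[str, int] = {}
    for node in tree.preorder():
        if node == gain_node:
            node_states[node] = 1
        elif node in loss_edges:
            node_states[node] = 0
        else:
            par = tree.parent(node)
            node_states[node] = 0 if par is None else node_states[par]

    return DolloReconstruction(character, gain_node, frozenset(loss_edges), node_states)


def count_independent_losses(recon: DolloReconstruction) -> int:
    """Number of independent loss events in a reconstruction."""
    return recon.n_losses


def map_characters(
    tree: Phylogeny, matrix: BinaryCharacterMatrix
) -> tuple[list[DolloReconstruction], str]:
    """Reconstruct every character in the matrix and annotate the tree.

    Returns the reconstructions (matrix column order) and a Newick string
    whose edges carry ``[&gain=...,loss=...]`` comments naming the
    characters gained or lost on each edge.
    """
    if not matrix.characters:
        raise InvalidArgumentError("empty character matrix")
    tipset = set(tree.tips)
    stray = [t for t in matrix.taxa if t not in tipset]
    if stray:
        raise NotFoundError(f"matrix taxa not in tree: {stray}")

    recons = [infer_dollo(tree, matrix.states(ch), ch) for ch in matrix.characters]

    gains: dict[str, list[str]] = {}
    losses: dict[str, list[str]] = {}
    for rec in recons:
        if rec.gain_edge is not None:
            gains.setdefault(rec.gain_edge, []).append(rec.character)
        for edge in sorted(rec.loss_edges):
            losses.setdefault(edge, []).append(rec.character)

    comments: dict[str, str] = {}
    for edge in set(gains) | set(losses):
        parts = []
        if edge in gains:
            parts.append("gain=" + "|".join(f"+{c}" for c in gains[edge]))
        if edge in losses:
            parts.append("loss=" + "|".join(f"-{c}" for c in losses[edge]))
        comments[edge] = "&" + ",".join(parts)

    return recons, tree.to_newick(comments)


def event_table(recons: Iterable[DolloReconstruction]) -> pd.DataFrame:
    """Long-format gain/loss event table (character, event, edge)."""
    rows = []
    for rec in recons:
        if rec.gain_edge is not None:
            rows.append((rec.character, "gain", rec.gain_edge))
        for edge in sorted(rec.loss_edges):
            rows.append((rec.character, "loss", edge))
    return pd.DataFrame(rows, columns=["character", "event", "edge"])
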