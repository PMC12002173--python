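"""Built-in worked example: PHLPP2 presence/absence across jawed vertebrates.

A coarse gnathostome species tree over major lineages, with the PHLPP2
gene scored present (1) or absent (0) per lineage.  The gene is absent
in caecilians, in squamates (snakes + lizards) and in two non-sister
turtle subclades separated by a retaining subclade, so Dollo parsimony
maps one gain at the root and four independent loss events — two of
them inside turtles on distinct edges.
"""

from __future__ import annotations

from .dollo import BinaryCharacterMatrix
from .phylo import Phylogeny, read_newick

__all__ = ["gnathostome_newick", "gnathostome_phlpp2"]

GNATHOSTOME_NEWICK = (
    "(sharks,(ray_finned_fishes,(coelacanths,((frogs,(salamanders,caecilians)"
    ")amphibia,(mammals,((snakes,lizards)squamata,((pleurodires,"
    "(softshell_turtles,(sea_turtles,tortoises))cryptodira)testudines,"
    "(crocodilians,birds)archosauria)archelosauria)reptilia)amniota)tetrapoda"
    ")sarcopterygii)osteichthyes)gnathostomata;"
)

#: lineages that have lost PHLPP2
_ABSENT = ("caecilians", "snakes", "lizards", "softshell_turtles", "tortoises")


def gnathostome_newick() -> str:
    return GNATHOSTOME_NEWICK


def gnathostome_phlpp2() -> tuple[Phylogeny, dict[str, int]]:
    """(species tree, PHLPP2 tip states) for the worked example."""
    tree = read_newick(GNATHOSTOME_NEWICK)
    states = {t: (0 if t in _ABSENT else 1) for t in tree.tips}
    return tree, states


def gnathostome_matrix() -> tuple[Phylogeny, BinaryCharacterMatrix]:
    tree, states = gnathostome_phlpp2()
    matrix = BinaryCharacterMatrix.from_states({"PHLPP2": states}, list(tree.tips))
    return tree, matrix
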