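import numpy as np
import pytest

from pseudolock.active_site import CatalyticSiteModel, SitePosition
from pseudolock.phylo import read_newick
from pseudolock.simulate import sim_tree


@pytest.fixture
def four_tip_tree():
    return read_newick("((A,B)ab,(C,D)cd)root;")


@pytest.fixture
def balanced_tree8():
    return sim_tree(8, seed=1)


@pytest.fixture
def site_model():
    """Synthetic metal-coordination model on a 30-residue reference."""
    return CatalyticSiteModel(
        reference_id="REF",
        sites=(
            SitePosition("M1", 5, frozenset("D"), True),
            SitePosition("M2", 12, frozenset("D"), True),
            SitePosition("M2", 18, frozenset("D"), True),
            SitePosition("M3", 25, frozenset("D"), False),
        ),
    )


def random_tip_states(tree, rng, p_one=0.5, p_missing=0.0):
    out = {}
    for t in tree.tips:
        u = rng.random()
        if u < p_missing:
            out[t] = None
        else:
            out[t] = 1 if rng.random() < p_one else 0
    return out
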