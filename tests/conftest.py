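import numpy as np
import pandas as pd
import pytest

from traitlink.ctmc import DependentRates, IndependentRates
from traitlink.phylo import parse_newick
from traitlink.traits import TraitTable


@pytest.fixture
def two_tip_tree():
    return parse_newick("(A:1.0,B:1.0);")


@pytest.fixture
def five_tip_tree():
    return parse_newick("((A:1.0,B:2.0):0.5,(C:1.5,(D:0.5,E:0.5):1.0):0.25);")


def make_traits(mapping):
    """mapping: taxon -> (habitat, leaf), values 0/1/-1."""
    df = pd.DataFrame(
        {t: {"habitat_state": hv, "leaf_state": lv} for t, (hv, lv) in mapping.items()}
    ).T
    df.index.name = "taxon"
    return TraitTable(df)


@pytest.fixture
def five_tip_traits():
    return make_traits({"A": (0, 0), "B": (0, 1), "C": (1, 0), "D": (1, 1), "E": (0, 0)})


def random_dependent_rates(rng, low=0.05, high=2.0):
    return DependentRates(*np.exp(rng.uniform(np.log(low), np.log(high), 8)))


def random_independent_rates(rng, low=0.05, high=2.0):
    return IndependentRates(*np.exp(rng.uniform(np.log(low), np.log(high), 4)))


def random_tree(rng, n_tips):
    """Random small rooted tree with random topology and branch lengths."""
    from traitlink.simulate import simulate_yule_tree

    return simulate_yule_tree(n_tips, 1.0, int(rng.integers(2**31 - 1)))
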