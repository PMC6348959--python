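"""Pruning likelihood against closed forms and the enumeration oracle."""

import numpy as np
import pytest

from conftest import (make_traits, random_dependent_rates,
                      random_independent_rates, random_tree)
from traitlink.ctmc import IndependentRates, expand_independent
from traitlink.likelihood import (RootPrior, binary_pruned_loglik,
                                  brute_force_loglik, pruned_loglik)
from traitlink.phylo import parse_newick
from traitlink.traits import MISSING

# frozen from the closed form 2*ln(((1+e^-2)/2)*((1-e^-2)/2)): two tips one
# unit apart, opposite states for both traits, symmetric unit rates
TWO_TIP_LOGLIK = -2.8095596


def test_all_missing_likelihood_is_one(two_tip_tree):
    traits = make_traits({"A": (MISSING, MISSING), "B": (MISSING, MISSING)})
    r = IndependentRates(1, 1, 1, 1)
    assert pruned_loglik(two_tip_tree, traits, r) == pytest.approx(0.0, abs=1e-12)


def test_two_tip_hand_value(two_tip_tree):
    traits = make_traits({"A": (0, 0), "B": (1, 1)})
    r = IndependentRates(1, 1, 1, 1)
    assert pruned_loglik(two_tip_tree, traits, r) == pytest.approx(TWO_TIP_LOGLIK, abs=1e-5)
    assert brute_force_loglik(two_tip_tree, traits, r) == pytest.approx(TWO_TIP_LOGLIK, abs=1e-5)


def test_single_tip_fixed_prior():
    tree = parse_newick("A:0.0;")
    traits = make_traits({"A": (1, 1)})  # combined state 4
    prior = RootPrior(kind="fixed", probs=(0.1, 0.2, 0.3, 0.4))
    r = random_dependent_rates(np.random.default_rng(0))
    assert brute_force_loglik(tree, traits, r, prior) == pytest.approx(np.log(0.4))


@pytest.mark.parametrize("seed", range(20))
def test_pruning_equals_enumeration(seed):
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, int(rng.integers(2, 6)))
    traits = make_traits({l: (int(rng.integers(2)), int(rng.integers(2)))
                          for l in tree.tip_labels})
    rates = random_dependent_rates(rng)
    assert pruned_loglik(tree, traits, rates) == pytest.approx(
        brute_force_loglik(tree, traits, rates), abs=1e-8)


@pytest.mark.parametrize("seed", range(10))
def test_independent_model_factorizes_per_trait(seed):
    rng = np.random.default_rng(seed + 1000)
    tree = random_tree(rng, int(rng.integers(4, 12)))
    states = {l: (int(rng.integers(2)), int(rng.integers(2))) for l in tree.tip_labels}
    traits = make_traits(states)
    r = random_independent_rates(rng)
    joint = pruned_loglik(tree, traits, r)
    hab = binary_pruned_loglik(tree, {k: v[0] for k, v in states.items()},
                               r.alpha1, r.beta1)
    leaf = binary_pruned_loglik(tree, {k: v[1] for k, v in states.items()},
                                r.alpha2, r.beta2)
    assert joint == pytest.approx(hab + leaf, abs=1e-8)


def test_dependent_expansion_matches_independent(five_tip_tree, five_tip_traits):
    rng = np.random.default_rng(4)
    r = random_independent_rates(rng)
    a = pruned_loglik(five_tip_tree, five_tip_traits, r)
    b = pruned_loglik(five_tip_tree, five_tip_traits, expand_independent(r))
    assert a == pytest.approx(b, abs=1e-10)


def test_missing_data_never_decreases_likelihood(five_tip_tree, five_tip_traits):
    r = random_dependent_rates(np.random.default_rng(9))
    full = pruned_loglik(five_tip_tree, five_tip_traits, r)
    for taxon in five_tip_traits.taxa:
        relaxed = five_tip_traits.data.copy()
        relaxed.loc[taxon] = [MISSING, MISSING]
        from traitlink.traits import TraitTable

        assert pruned_loglik(five_tip_tree, TraitTable(relaxed), r) >= full - 1e-12


def test_child_order_invariance(five_tip_traits):
    r = random_dependent_rates(np.random.default_rng(2))
    t1 = parse_newick("((A:1.0,B:2.0):0.5,(C:1.5,(D:0.5,E:0.5):1.0):0.25);")
    t2 = parse_newick("(((E:0.5,D:0.5):1.0,C:1.5):0.25,(B:2.0,A:1.0):0.5);")
    assert pruned_loglik(t1, five_tip_traits, r) == pytest.approx(
        pruned_loglik(t2, five_tip_traits, r), abs=1e-10)


def test_missing_tip_in_traits_is_an_error(five_tip_tree):
    traits = make_traits({"A": (0, 0), "B": (0, 1)})
    with pytest.raises(ValueError, match="absent"):
        pruned_loglik(five_tip_tree, traits, IndependentRates(1, 1, 1, 1))


def test_brute_force_refuses_large_trees():
    rng = np.random.default_rng(11)
    tree = random_tree(rng, 12)
    traits = make_traits({l: (0, 0) for l in tree.tip_labels})
    with pytest.raises(ValueError, match="enumeration"):
        brute_force_loglik(tree, traits, IndependentRates(1, 1, 1, 1))


def test_conflicting_tips_on_zero_length_tree():
    tree = parse_newick("(A:0.0,B:0.0);")
    traits = make_traits({"A": (0, 0), "B": (1, 1)})
    r = IndependentRates(1, 1, 1, 1)
    assert pruned_loglik(tree, traits, r) == -np.inf
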