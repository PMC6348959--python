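"""Hypothesis-test layer and the parsimony minimum-origins counter."""

import numpy as np
import pytest

from conftest import make_traits, random_tree
from traitlink.bayes import MCMCConfig, PriorSpec
from traitlink.ctmc import RATE_NAMES, DependentRates
from traitlink.hypotheses import (CANONICAL_CONTRASTS, OPPOSITE_PAIRS,
                                  TestReport, all_single_restrictions,
                                  correlation_test, count_min_transitions,
                                  restriction_test, temporal_order_test)
from traitlink.ml import Constraint, MLConfig
from traitlink.phylo import parse_newick
from traitlink.simulate import simulate_traits, simulate_yule_tree
from traitlink.validation import enumerate_min_changes

CFG = MLConfig(n_tries=24, n_repeats=1, seed=5, refine_top=2)


@pytest.fixture(scope="module")
def dataset():
    tree = simulate_yule_tree(20, 1.0, 17)
    rates = DependentRates(0.3, 0.1, 0.2, 0.8, 0.2, 0.4, 0.2, 0.2)
    return tree, simulate_traits(tree, rates, root=1, seed=18)


def test_correlation_report_schema(dataset):
    tree, traits = dataset
    rep = correlation_test(tree, traits, "ml", CFG)
    assert rep.method == "ml"
    assert rep.df == 4
    assert 0 <= rep.p_value <= 1
    assert rep.statistic >= 0
    assert rep.null_model == "independent" and rep.alt_model == "dependent"
    assert rep.support is None


def test_restriction_nesting_and_df(dataset):
    tree, traits = dataset
    rep = restriction_test(tree, traits, Constraint.fix_zero("q13"), "ml", CFG)
    assert rep.df == 1
    assert rep.statistic >= 0
    assert rep.loglik_null <= rep.loglik_alt + 1e-6
    assert rep.rates_null["q13"] == 0.0


def test_temporal_order_contrasts_and_errors(dataset):
    tree, traits = dataset
    rep = temporal_order_test(tree, traits, ("q12", "q13"), "ml", CFG)
    assert rep.name == "temporal_order[q12~q13]"
    with pytest.raises(ValueError, match="q14"):
        temporal_order_test(tree, traits, ("q14", "q13"), "ml", CFG)
    with pytest.raises(ValueError, match="distinct"):
        temporal_order_test(tree, traits, ("q12", "q12"), "ml", CFG)
    assert set(CANONICAL_CONTRASTS) == {
        "first_change_from_00", "habitat_gain_contingent_on_leaf",
        "leaf_gain_contingent_on_habitat"}


def test_all_single_restrictions_cover_twelve(dataset):
    tree, traits = dataset
    small = MLConfig(n_tries=8, n_repeats=1, seed=5, refine_top=1)
    reports = all_single_restrictions(tree, traits, "ml", small)
    assert len(reports) == 12
    fixed = [r for r in reports if "=0" in r.null_constraints[0]]
    assert len(fixed) == 8
    assert {r.null_constraints[0] for r in reports[8:]} == \
        {f"{a}={b}" for a, b in OPPOSITE_PAIRS}
    assert all(r.statistic >= 0 and r.df == 1 for r in reports)


def test_mcmc_report_carries_support(dataset):
    tree, traits = dataset
    cfg = MCMCConfig(iterations_per_stone=150, n_stones=6, n_repeats=1, seed=2)
    rep = correlation_test(tree, traits, "mcmc", cfg, PriorSpec("exponential"))
    assert rep.method == "mcmc"
    assert rep.support in {"none", "positive", "strong", "very strong"}
    assert rep.p_value is None and rep.df is None


def test_report_roundtrip(dataset):
    tree, traits = dataset
    rep = restriction_test(tree, traits, Constraint.fix_zero("q24"), "ml", CFG)
    back = TestReport.from_dict(rep.to_dict())
    assert back.name == rep.name
    assert back.statistic == pytest.approx(rep.statistic, abs=1e-4)
    assert back.p_value == rep.p_value
    assert back.rates_alt == {k: float(v) for k, v in rep.rates_alt.items()}


# -- parsimony ------------------------------------------------------------

def test_fitch_trivial_cases():
    tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert count_min_transitions(tree, dict(A=0, B=0, C=0, D=0)).min_changes == 0
    assert count_min_transitions(tree, dict(A=1, B=0, C=1, D=0)).min_changes == 2
    star = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
    res = count_min_transitions(star, dict(A=1, B=0, C=0, D=0, E=0))
    assert res.min_changes == 1
    assert res.min_gains_root0 == 1


def test_fitch_missing_and_empty():
    tree = parse_newick("((A:1,B:1):1,C:1);")
    from traitlink.traits import MISSING

    res = count_min_transitions(tree, dict(A=1, B=MISSING, C=0))
    assert res.min_changes == 1
    with pytest.raises(ValueError, match="no scored tips"):
        count_min_transitions(tree, dict(A=MISSING, B=MISSING, C=MISSING))


@pytest.mark.parametrize("seed", range(15))
def test_fitch_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, int(rng.integers(3, 9)))
    character = {l: int(rng.integers(2)) for l in tree.tip_labels}
    fast = count_min_transitions(tree, character).min_changes
    assert fast == enumerate_min_changes(tree, character)


def test_min_gains_with_root_zero():
    # gain on the stem of (C,D) plus a loss inside is one gain;
    # two parallel gains would also give 2 changes but more gains
    tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    res = count_min_transitions(tree, dict(A=0, B=0, C=1, D=1))
    assert res.min_changes == 1
    assert res.min_gains_root0 == 1
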