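"""MCMC sampling and stepping-stone marginal likelihoods."""

import numpy as np
import pytest

from conftest import make_traits
from traitlink.bayes import (MCMCConfig, PriorSpec, interpret_log_bf,
                             log_bayes_factor, run_mcmc, stepping_stone,
                             _stone_powers)
from traitlink.traits import MISSING
from traitlink.validation import (one_parameter_fixture,
                                  quadrature_log_marginal)

FAST = MCMCConfig(iterations=8000, burn_in=0.25, thinning=20,
                  iterations_per_stone=400, n_stones=12, n_repeats=2, seed=3)


def test_log_bayes_factor_paper_arithmetic():
    assert log_bayes_factor(-29.15, -36.85) == pytest.approx(15.40, abs=1e-9)
    assert log_bayes_factor(-28.84, -32.73) == pytest.approx(7.78, abs=1e-9)
    assert log_bayes_factor(-5.0, -5.0) == 0.0
    # antisymmetry
    assert log_bayes_factor(-1.2, -3.4) == -log_bayes_factor(-3.4, -1.2)


@pytest.mark.parametrize("value,category", [
    (5.34, "strong"), (2.05, "positive"), (1.0, "none"), (15.4, "very strong"),
    (2.0, "positive"), (5.0, "strong"), (10.0, "very strong"), (-3.0, "none"),
])
def test_support_categories(value, category):
    assert interpret_log_bf(value) == category


def test_stone_powers_increase_from_zero_to_one():
    p = _stone_powers(100)
    assert p[0] == 0.0 and p[-1] == 1.0
    assert np.all(np.diff(p) > 0)
    # Beta(0.4, 1) quantiles concentrate near the prior
    assert p[50] < 0.2


def test_mcmc_deterministic_and_tuned():
    tree, traits, cons = one_parameter_fixture()
    a = run_mcmc(tree, traits, "dependent", cons, PriorSpec("exponential"), FAST)
    b = run_mcmc(tree, traits, "dependent", cons, PriorSpec("exponential"), FAST)
    assert np.array_equal(a.samples, b.samples)
    assert np.array_equal(a.logliks, b.logliks)
    assert 0.1 < a.acceptance < 0.6


def test_mcmc_gamma_hyper_prior_runs():
    tree, traits, cons = one_parameter_fixture()
    tr = run_mcmc(tree, traits, "dependent", cons, PriorSpec("gamma_hyper"), FAST)
    assert tr.hyper_samples.shape[1] == 2
    assert (tr.hyper_samples > 0).all() and (tr.hyper_samples <= 10).all()
    assert 0.05 < tr.acceptance < 0.7


def test_stepping_stone_flat_likelihood_returns_zero():
    tree, _, cons = one_parameter_fixture()
    traits = make_traits({l: (MISSING, MISSING) for l in tree.tip_labels})
    for prior in (PriorSpec("exponential"), PriorSpec("gamma_hyper")):
        res = stepping_stone(tree, traits, "dependent", cons, prior,
                             MCMCConfig(iterations_per_stone=200, n_stones=8,
                                        n_repeats=1, seed=1))
        assert res.log_marginal == pytest.approx(0.0, abs=1e-6)


def test_stepping_stone_matches_quadrature():
    tree, traits, cons = one_parameter_fixture()
    oracle = quadrature_log_marginal(tree, traits, prior_mean=10.0)
    cfg = MCMCConfig(iterations_per_stone=500, n_stones=16, n_repeats=2, seed=11)
    res = stepping_stone(tree, traits, "dependent", cons,
                         PriorSpec("exponential", mean=10.0), cfg)
    assert res.log_marginal == pytest.approx(oracle, abs=0.1)
    assert len(res.per_repeat) == 2
    assert np.isclose(res.log_marginal, np.mean(res.per_repeat))


def test_repeat_spread_is_small_on_fixture():
    tree, traits, cons = one_parameter_fixture()
    cfg = MCMCConfig(iterations_per_stone=400, n_stones=12, n_repeats=4, seed=5)
    res = stepping_stone(tree, traits, "dependent", cons,
                         PriorSpec("exponential"), cfg)
    assert np.std(res.per_repeat) < 0.5


def test_more_stones_reduce_variance_at_fixed_budget():
    # the stone ladder pays off when the posterior is far from the prior:
    # with a diffuse uniform prior and a sharp 100-tip likelihood, plain
    # prior importance sampling (K=1) is noisy while the tempered ladder
    # at the same total sample budget is stable
    from traitlink.ctmc import RATE_NAMES, DependentRates
    from traitlink.ml import Constraint
    from traitlink.simulate import simulate_traits, simulate_yule_tree

    tree = simulate_yule_tree(100, 1.0, 314)
    traits = simulate_traits(tree, DependentRates(*[0.3] * 8), root=1, seed=315)
    cons = [Constraint.equal_pair("q12", n) for n in RATE_NAMES[1:]]
    prior = PriorSpec("uniform", bounds=(1e-8, 100.0))
    ests = {K: [] for K in (1, 16)}
    for K in ests:
        for seed in range(8):
            cfg = MCMCConfig(iterations_per_stone=3200 // K, n_stones=K,
                             n_repeats=1, seed=seed + 20)
            ests[K].append(stepping_stone(tree, traits, "dependent", cons,
                                          prior, cfg).log_marginal)
    assert np.std(ests[16]) < np.std(ests[1])
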