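"""Hypothesis-testing layer: correlation, parameter-restriction and
temporal-order tests, plus the minimum-origins parsimony counter.

Every test is a comparison of two nested model fits.  With ``method='ml'``
the statistic is the likelihood ratio with a chi-square p-value (df = number
of constrained dimensions); with ``method='mcmc'`` it is the log Bayes
factor from stepping-stone marginal likelihoods, graded on the 2/5/10
support scale.  The temporal-order and contingent-change questions are all
equality restrictions between named rates; the canonical contrasts are

* ``q12`` vs ``q13`` — which trait tends to change first from state (0,0);
* ``q13`` vs ``q24`` — is the habitat shift contingent on leaf shape;
* ``q12`` vs ``q34`` — is the leaf-shape change contingent on habitat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np

from .bayes import (MCMCConfig, PriorSpec, interpret_log_bf, log_bayes_factor,
                    stepping_stone)
from .ctmc import RATE_NAMES
from .likelihood import RootPrior
from .ml import Constraint, MLConfig, fit_ml, lrt
from .phylo import PhyloTree
from .traits import MISSING, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "TestReport", "CANONICAL_CONTRASTS", "OPPOSITE_PAIRS",
    "correlation_test", "restriction_test", "temporal_order_test",
    "all_single_restrictions", "ParsimonyResult", "count_min_transitions",
]

#: Named temporal-order / contingent-change contrasts.
CANONICAL_CONTRASTS = {
    "first_change_from_00": ("q12", "q13"),
    "habitat_gain_contingent_on_leaf": ("q13", "q24"),
    "leaf_gain_contingent_on_habitat": ("q12", "q34"),
}

#: Forward/backward rate pairs for the "opposite rates equal" tests.
OPPOSITE_PAIRS = (("q12", "q21"), ("q13", "q31"), ("q24", "q42"), ("q34", "q43"))


@dataclass
class TestReport:
    """A single nested-model comparison and its verdict."""

    __test__ = False  # not a pytest collectable

    name: str
    method: str                      # 'ml' | 'mcmc'
    null_constraints: list[str]
    alt_constraints: list[str]
    null_model: str
    alt_model: str
    loglik_null: float               # log-likelihood (ml) or log marginal likelihood (mcmc)
    loglik_alt: float
    statistic: float                 # LR or log Bayes factor
    df: int | None = None
    p_value: float | None = None
    support: str | None = None
    verdict: str = ""
    rates_alt: dict = field(default_factory=dict)
    rates_null: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method == "ml" and self.p_value is None:
            raise ValueError("ml reports carry a p-value")
        if self.method == "mcmc" and self.support is None:
            raise ValueError("mcmc reports carry a support category")
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["statistic"] = round(self.statistic, 4)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TestReport":
        return cls(**d)


def _ml_report(name, tree, traits, null_model, null_cons, alt_model, alt_cons,
               df, config, root_prior, alpha=0.05):
    null = fit_ml(tree, traits, null_model, null_cons, config, root_prior)
    # warm-start the alternative from the null optimum: guarantees the
    # nesting inequality holds numerically, not just in expectation
    alt = fit_ml(tree, traits, alt_model, alt_cons, config, root_prior,
                 extra_starts=(null.rates,))
    stat, p = lrt(null.loglik, alt.loglik, df)
    verdict = ("significant (reject null)" if p < alpha
               else "no significant difference")
    return TestReport(
        name=name, method="ml",
        null_constraints=[c.label() for c in null_cons],
        alt_constraints=[c.label() for c in alt_cons],
        null_model=null_model, alt_model=alt_model,
        loglik_null=null.loglik, loglik_alt=alt.loglik,
        statistic=stat, df=df, p_value=p, verdict=verdict,
        rates_alt=alt.rates.as_dict(), rates_null=null.rates.as_dict(),
        seed=config.seed,
    )


def _mcmc_report(name, tree, traits, null_model, null_cons, alt_model, alt_cons,
                 prior, config, root_prior):
    null = stepping_stone(tree, traits, null_model, null_cons, prior, config, root_prior)
    alt = stepping_stone(tree, traits, alt_model, alt_cons, prior, config, root_prior)
    bf = log_bayes_factor(alt.log_marginal, null.log_marginal)
    support = interpret_log_bf(bf)
    verdict = (f"{support} support for the alternative" if support != "none"
               else "no support for the alternative")
    return TestReport(
        name=name, method="mcmc",
        null_constraints=[c.label() for c in null_cons],
        alt_constraints=[c.label() for c in alt_cons],
        null_model=null_model, alt_model=alt_model,
        loglik_null=null.log_marginal, loglik_alt=alt.log_marginal,
        statistic=bf, support=support, verdict=verdict,
        seed=config.seed,
    )


def correlation_test(tree: PhyloTree, traits: TraitTable, method: str = "ml",
                     config: MLConfig | MCMCConfig | None = None,
                     prior: PriorSpec = PriorSpec(),
                     root_prior: RootPrior = RootPrior()) -> TestReport:
    """Dependent vs independent model: are the two characters correlated?

    The independent model (4 rates) is the null, the dependent model
    (8 rates) the alternative; ml uses the df-4 LRT, mcmc the log Bayes
    factor between stepping-stone marginal likelihoods.
    """
    if method == "ml":
        cfg = config or MLConfig()
        verdictless = _ml_report("correlation", tree, traits,
                                 "independent", (), "dependent", (), 4,
                                 cfg, root_prior)
        verdictless.verdict = ("significant correlation"
                               if verdictless.p_value < 0.05
                               else "no significant correlation")
        return verdictless
    if method == "mcmc":
        cfg = config or MCMCConfig()
        rep = _mcmc_report("correlation", tree, traits,
                           "independent", (), "dependent", (),
                           prior, cfg, root_prior)
        rep.verdict = (f"correlation supported ({rep.support})"
                       if rep.support != "none" else "no significant correlation")
        return rep
    raise ValueError(f"method must be 'ml' or 'mcmc', got {method!r}")


def restriction_test(tree: PhyloTree, traits: TraitTable, constraint: Constraint,
                     method: str = "ml",
                     config: MLConfig | MCMCConfig | None = None,
                     prior: PriorSpec = PriorSpec(),
                     root_prior: RootPrior = RootPrior()) -> TestReport:
    """Full dependent model vs dependent model plus one restriction (df 1)."""
    _validate_dependent_names(constraint.params)
    name = f"restriction[{constraint.label()}]"
    if method == "ml":
        return _ml_report(name, tree, traits, "dependent", (constraint,),
                          "dependent", (), 1, config or MLConfig(), root_prior)
    if method == "mcmc":
        return _mcmc_report(name, tree, traits, "dependent", (constraint,),
                            "dependent", (), prior, config or MCMCConfig(), root_prior)
    raise ValueError(f"method must be 'ml' or 'mcmc', got {method!r}")


def temporal_order_test(tree: PhyloTree, traits: TraitTable,
                        contrast: tuple[str, str], method: str = "ml",
                        config=None, prior: PriorSpec = PriorSpec(),
                        root_prior: RootPrior = RootPrior()) -> TestReport:
    """Equality restriction between two named dependent-model rates."""
    a, b = contrast
    _validate_dependent_names((a, b))
    if a == b:
        raise ValueError("contrast must name two distinct rates")
    rep = restriction_test(tree, traits, Constraint.equal_pair(a, b),
                           method, config, prior, root_prior)
    rep.name = f"temporal_order[{a}~{b}]"
    return rep


def all_single_restrictions(tree: PhyloTree, traits: TraitTable,
                            method: str = "ml", config=None,
                            prior: PriorSpec = PriorSpec(),
                            root_prior: RootPrior = RootPrior()) -> list[TestReport]:
    """The eight fix-zero tests plus the four opposite-pair equality tests."""
    reports = []
    for name in RATE_NAMES:
        reports.append(restriction_test(tree, traits, Constraint.fix_zero(name),
                                        method, config, prior, root_prior))
    for a, b in OPPOSITE_PAIRS:
        reports.append(restriction_test(tree, traits, Constraint.equal_pair(a, b),
                                        method, config, prior, root_prior))
    return reports


def _validate_dependent_names(names) -> None:
    bad = [n for n in names if n not in RATE_NAMES]
    if bad:
        raise ValueError(f"not dependent-model rates: {bad}; valid: {list(RATE_NAMES)}")


# ---------------------------------------------------------------------------
# Minimum-origins (parsimony) counter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsimonyResult:
    """Minimum state changes on the rooted tree, and minimum 0->1 gains
    among those reconstructions when the root is fixed at state 0."""

    min_changes: int
    min_gains_root0: int

    def __int__(self) -> int:
        return self.min_changes


def count_min_transitions(tree: PhyloTree, character: dict[str, int]) -> ParsimonyResult:
    """Small-parsimony count of changes for one binary character.

    Unit-cost Sankoff dynamic programming (exact for polytomies); tips with
    missing state are treated as free (warning logged); an all-missing
    character is an error.  Ties in total changes are resolved toward the
    fewest 0->1 gains for the reported gain count.
    """
    idx = tree.index()
    observed = {l: s for l, s in character.items()
                if l in idx.tip_label_to_id and s != MISSING}
    if not observed:
        raise ValueError("character has no scored tips")
    n_free = len(idx.tip_label_to_id) - len(observed)
    if n_free:
        logger.warning("%d tips unscored; treated as free states", n_free)

    INF = (10**9, 10**9)
    # cost[i][s] = (changes, gains) lexicographic minimum for subtree i with node state s
    cost = np.empty((idx.n_nodes, 2), dtype=object)
    children = idx.children()
    for i in range(idx.n_nodes):
        if idx.is_tip[i]:
            label = next(l for l, j in idx.tip_label_to_id.items() if j == i)
            s_obs = observed.get(label)
            for s in (0, 1):
                cost[i][s] = (0, 0) if (s_obs is None or s_obs == s) else INF
        else:
            for s in (0, 1):
                ch, gn = 0, 0
                for c in children[i]:
                    best = INF
                    for sc in (0, 1):
                        cc, gc = cost[c][sc]
                        if sc != s:
                            cc += 1
                            if s == 0 and sc == 1:
                                gc += 1
                        if (cc, gc) < best:
                            best = (cc, gc)
                    ch += best[0]
                    gn += best[1]
                cost[i][s] = (ch, gn)
    root = idx.root
    min_changes = min(cost[root][0][0], cost[root][1][0])
    return ParsimonyResult(min_changes=int(min_changes),
                           min_gains_root0=int(cost[root][0][1]))
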