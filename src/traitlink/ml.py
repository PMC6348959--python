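"""Maximum-likelihood fitting with multi-start restarts and rate constraints.

Rates are optimized on a log scale (they span orders of magnitude) within
bounds [1e-8, 1e3].  Each of ``n_repeats`` repeats draws ``n_tries``
log-uniform starting points, ranks them by likelihood, and refines the best
``refine_top`` with L-BFGS-B; ties across restarts are broken first-found
in seed order, so results are bit-reproducible for a given seed.

Constraints restrict the dependent model: ``fix_zero`` pins a rate at
exactly 0; ``equal_pair`` ties two rates to one free parameter (transitively,
so chains of pairs collapse whole groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .ctmc import RATE_NAMES, DependentRates, IndependentRates
from .likelihood import PruningEngine, RootPrior
from .phylo import PhyloTree
from .traits import TraitTable

logger = logging.getLogger(__name__)

__all__ = ["MLConfig", "Constraint", "Parameterization", "MLResult", "fit_ml", "lrt"]

INDEP_NAMES = ("alpha1", "beta1", "alpha2", "beta2")


@dataclass(frozen=True)
class MLConfig:
    """Multi-start search settings (defaults follow the 1000-tries, 10-repeats design)."""

    n_tries: int = 1000
    n_repeats: int = 10
    seed: int = 0
    rate_bounds: tuple[float, float] = (1e-8, 1e3)
    refine_top: int = 10  # starts refined by local optimization, per repeat

    def __post_init__(self) -> None:
        lo, hi = self.rate_bounds
        if self.n_tries < 1 or self.n_repeats < 1:
            raise ValueError("n_tries and n_repeats must be >= 1")
        if not (0 < lo < hi):
            raise ValueError("rate bounds must be positive with lower < upper")


@dataclass(frozen=True)
class Constraint:
    """fix_zero(q) pins one rate at 0; equal_pair(a, b) equates two rates."""

    kind: str
    params: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind == "fix_zero":
            if len(self.params) != 1:
                raise ValueError("fix_zero takes exactly one parameter")
        elif self.kind == "equal_pair":
            if len(self.params) != 2 or self.params[0] == self.params[1]:
                raise ValueError("equal_pair takes two distinct parameters")
        else:
            raise ValueError(f"unknown constraint kind {self.kind!r}")

    @classmethod
    def fix_zero(cls, name: str) -> "Constraint":
        return cls("fix_zero", (name,))

    @classmethod
    def equal_pair(cls, a: str, b: str) -> "Constraint":
        return cls("equal_pair", (a, b))

    def label(self) -> str:
        if self.kind == "fix_zero":
            return f"{self.params[0]}=0"
        return f"{self.params[0]}={self.params[1]}"


class Parameterization:
    """Maps a free-parameter vector to a full rate object under constraints."""

    def __init__(self, model: str, constraints=()):
        if model not in ("dependent", "independent"):
            raise ValueError(f"model must be 'dependent' or 'independent', got {model!r}")
        self.model = model
        self.constraints = tuple(constraints)
        names = RATE_NAMES if model == "dependent" else INDEP_NAMES
        valid = set(names)
        for c in self.constraints:
            for p in c.params:
                if p not in valid:
                    raise ValueError(f"parameter {p!r} invalid for the {model} model")
        # union-find over names for equality groups
        rep = {n: n for n in names}

        def find(x):
            while rep[x] != x:
                rep[x] = rep[rep[x]]
                x = rep[x]
            return x

        for c in self.constraints:
            if c.kind == "equal_pair":
                a, b = (find(p) for p in c.params)
                if a != b:
                    rep[max(a, b)] = min(a, b)
        zero_groups = set()
        for c in self.constraints:
            if c.kind == "fix_zero":
                zero_groups.add(find(c.params[0]))
        for g in zero_groups:
            members = [n for n in names if find(n) == g]
            if len(members) > 1:
                raise ValueError(
                    f"infeasible constraints: {members} equated but also fixed to zero"
                )
        self._group_of = {n: find(n) for n in names}
        self._zero = {n for n in names if self._group_of[n] in zero_groups}
        self.free_names = sorted({self._group_of[n] for n in names if n not in self._zero})
        self._names = names

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def project(self, rates: "DependentRates | IndependentRates") -> np.ndarray:
        """Free-parameter vector nearest a full rate object (group means).

        Used to warm-start a fit from a nested model's optimum: any
        independent-model solution, and any solution of a more constrained
        dependent model, maps to a feasible point of this parameterization.
        """
        d = rates.as_dict()
        if self.model == "dependent" and isinstance(rates, IndependentRates):
            from .ctmc import expand_independent

            d = expand_independent(rates).as_dict()
        out = []
        for g in self.free_names:
            members = [n for n in self._names if self._group_of[n] == g]
            out.append(float(np.mean([d[m] for m in members])))
        return np.array(out)

    def to_rates(self, free_values) -> DependentRates | IndependentRates:
        v = dict(zip(self.free_names, np.asarray(free_values, dtype=float)))
        full = {
            n: 0.0 if n in self._zero else float(v[self._group_of[n]])
            for n in self._names
        }
        cls = DependentRates if self.model == "dependent" else IndependentRates
        return cls(**full)


@dataclass
class MLResult:
    """Outcome of a multi-start ML fit."""

    model: str
    constraints: tuple[Constraint, ...]
    loglik: float                       # max over repeats
    loglik_mean: float                  # mean of per-repeat bests
    per_repeat: list[float]
    rates: DependentRates | IndependentRates
    config: MLConfig
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "constraints": [c.label() for c in self.constraints],
            "loglik": round(self.loglik, 6),
            "loglik_mean": round(self.loglik_mean, 6),
            "per_repeat": [round(v, 6) for v in self.per_repeat],
            "rates": {k: float(v) for k, v in self.rates.as_dict().items()},
            "seed": self.config.seed,
            "n_tries": self.config.n_tries,
            "n_repeats": self.config.n_repeats,
            "converged": self.converged,
        }


def _polish(negll, x0, lo, hi, n_free):
    """Two-stage local search: L-BFGS-B then a Nelder-Mead polish.

    The log-likelihood surface of the 8-rate model has curved ridges on
    which quasi-Newton steps with finite-difference gradients terminate
    early; the simplex polish walks along them reliably at these dimensions.
    """
    r1 = minimize(negll, x0, method="L-BFGS-B",
                  bounds=[(lo, hi)] * n_free, options={"eps": 1e-6})
    r2 = minimize(negll, r1.x, method="Nelder-Mead",
                  options=dict(maxfev=250 * n_free, fatol=1e-8, xatol=1e-6,
                               adaptive=n_free > 2))
    best = r2 if r2.fun <= r1.fun else r1
    return np.clip(best.x, lo, hi), -float(best.fun), bool(r1.success or r2.success)


def fit_ml(tree: PhyloTree, traits: TraitTable, model: str = "dependent",
           constraints=(), config: MLConfig = MLConfig(),
           root_prior: RootPrior = RootPrior(),
           extra_starts=()) -> MLResult:
    """Fit the dependent or independent model by constrained multi-start ML.

    ``extra_starts`` may hold rate objects (for instance a nested model's
    optimum) that are always refined in addition to the best random starts.
    """
    param = Parameterization(model, constraints)
    engine = PruningEngine(tree, traits, root_prior)
    lo, hi = np.log(config.rate_bounds[0]), np.log(config.rate_bounds[1])

    if param.n_free == 0:  # everything fixed: nothing to optimize
        ll = engine.loglik(param.to_rates([]))
        return MLResult(model, param.constraints, ll, ll, [ll],
                        param.to_rates([]), config, True)

    def negll(logx: np.ndarray) -> float:
        v = engine.loglik(param.to_rates(np.exp(np.clip(logx, lo, hi))))
        return 1e300 if not np.isfinite(v) else -v

    warm = [np.clip(np.log(np.maximum(param.project(r), config.rate_bounds[0])), lo, hi)
            for r in extra_starts]

    per_repeat: list[float] = []
    best_ll = -np.inf
    best_x: np.ndarray | None = None
    any_converged = False
    for rep in range(config.n_repeats):
        rng = np.random.default_rng([config.seed, rep])
        starts = rng.uniform(lo, hi, size=(config.n_tries, param.n_free))
        vals = np.array([negll(s) for s in starts])
        order = np.argsort(vals, kind="stable")[: min(config.refine_top, config.n_tries)]
        rep_best = -np.inf
        rep_x = starts[order[0]]
        for x0 in warm + [starts[k] for k in order]:
            x, ll, ok = _polish(negll, x0, lo, hi, param.n_free)
            any_converged = any_converged or ok
            if ll > rep_best:
                rep_best = ll
                rep_x = x
        per_repeat.append(rep_best)
        if rep_best > best_ll:
            best_ll = rep_best
            best_x = rep_x
    if not any_converged:
        raise RuntimeError("optimizer failed to converge from every start; "
                           "check the data for degenerate structure")
    return MLResult(model, param.constraints, best_ll, float(np.mean(per_repeat)),
                    per_repeat, param.to_rates(np.exp(best_x)), config, any_converged)


def lrt(loglik_null: float, loglik_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic 2(l1 - l0), clamped at 0, and its chi-square p-value."""
    if df < 1:
        raise ValueError("df must be a positive integer")
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < 0:
        logger.warning("negative LR statistic %.6g clamped to 0 "
                       "(null fit exceeded alternative)", stat)
        stat = 0.0
    return stat, float(chi2.sf(stat, df))
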