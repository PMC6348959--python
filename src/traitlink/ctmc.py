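"""Two-trait continuous-time Markov models (Pagel's discrete framework).

The pair (habitat, leaf) is collapsed to one combined state indexed 1..4
(aliases A..D): 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1).  The *dependent* model
has eight free transition rates q12, q13, q21, q24, q31, q34, q42, q43 —
each trait's rate may depend on the current state of the other trait.
Simultaneous double changes (1<->4, 2<->3) are forbidden, so those
generator entries are structurally zero.  The *independent* model is the
nested 4-parameter special case q13=q24=alpha1, q31=q42=beta1,
q12=q34=alpha2, q21=q43=beta2.

Rates are events per unit branch length of the input tree; no internal
rescaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import expm

__all__ = [
    "RATE_NAMES",
    "STATE_ALIASES",
    "DependentRates",
    "IndependentRates",
    "expand_independent",
    "build_Q",
    "transition_matrix",
    "transition_matrices",
    "stationary_distribution",
    "ReducibleChainError",
]

#: Canonical dependent-model rate names, in fixed order.
RATE_NAMES = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")

#: Combined-state display aliases in index order 1..4.
STATE_ALIASES = ("A", "B", "C", "D")

# (from, to) combined-state indices (0-based) for each rate name.
_TRANSITIONS = {
    "q12": (0, 1), "q13": (0, 2), "q21": (1, 0), "q24": (1, 3),
    "q31": (2, 0), "q34": (2, 3), "q42": (3, 1), "q43": (3, 2),
}


def _check_nonneg(**rates: float) -> None:
    for name, v in rates.items():
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"rate {name} must be a finite non-negative real, got {v}")


@dataclass(frozen=True)
class DependentRates:
    """Eight transition rates of the dependent model (events per unit branch length)."""

    q12: float
    q13: float
    q21: float
    q24: float
    q31: float
    q34: float
    q42: float
    q43: float

    def __post_init__(self) -> None:
        _check_nonneg(**self.as_dict())

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in RATE_NAMES}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in RATE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, v) -> "DependentRates":
        v = np.asarray(v, dtype=float)
        if v.shape != (8,):
            raise ValueError("dependent rate vector must have length 8")
        return cls(**dict(zip(RATE_NAMES, v)))


@dataclass(frozen=True)
class IndependentRates:
    """Trait-specific rates: habitat gain/loss (alpha1/beta1), leaf gain/loss (alpha2/beta2)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float

    def __post_init__(self) -> None:
        _check_nonneg(**asdict(self))

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    def as_vector(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2], dtype=float)


def expand_independent(r: IndependentRates) -> DependentRates:
    """Embed the independent model in the dependent parameterization.

    Habitat changes at alpha1/beta1 and leaf at alpha2/beta2 irrespective of
    the other trait: q13=q24=alpha1, q31=q42=beta1, q12=q34=alpha2,
    q21=q43=beta2.  The nesting is exact, so likelihoods agree.
    """
    return DependentRates(
        q12=r.alpha2, q13=r.alpha1, q21=r.beta2, q24=r.alpha1,
        q31=r.beta1, q34=r.alpha2, q42=r.beta1, q43=r.beta2,
    )


def build_Q(r: DependentRates | IndependentRates) -> np.ndarray:
    """4x4 generator over combined states 1..4; rows sum to zero.

    Entries for the forbidden double transitions (1<->4, 2<->3) are zero.
    """
    if isinstance(r, IndependentRates):
        r = expand_independent(r)
    Q = np.zeros((4, 4), dtype=float)
    for name, (i, j) in _TRANSITIONS.items():
        Q[i, j] = getattr(r, name)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Q t) by scaling-and-squaring Pade (scipy.linalg.expm)."""
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    if t == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    np.clip(P, 0.0, 1.0, out=P)
    return P


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) for a batch of branch lengths.

    Uses one eigendecomposition of Q when it is well conditioned (the
    generic case for these 4x4 generators), falling back to per-branch Pade
    exponentials otherwise.  Rows are renormalized clips of the exact
    exponential; row-sum error before clipping is kept below 1e-10.
    """
    ts = np.asarray(ts, dtype=float)
    if (ts < 0).any():
        raise ValueError("branch lengths must be non-negative")
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        # cheap 1-norm condition proxy; the row-sum check below is the
        # authoritative accuracy guard
        cond1 = np.abs(V).sum(axis=0).max() * np.abs(Vinv).sum(axis=0).max()
        if cond1 < 1e8:
            E = np.exp(np.multiply.outer(ts, w))          # (n, 4)
            P = np.einsum("ij,nj,jk->nik", V, E, Vinv).real
            rows = P.sum(axis=2)
            if np.abs(rows - 1.0).max() < 1e-9 and P.min() > -1e-9:
                return np.clip(P, 0.0, 1.0)
    except np.linalg.LinAlgError:
        pass
    return np.stack([transition_matrix(Q, float(t)) for t in ts])


class ReducibleChainError(ValueError):
    """The chain is not irreducible; use a uniform or fixed root prior instead."""


def _strongly_connected(Q: np.ndarray) -> bool:
    adj = Q > 0
    n = Q.shape[0]

    def reach(mat, start=0):
        seen = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for j in range(n):
                if mat[i, j] and j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n

    return reach(adj) and reach(adj.T)


def stationary_distribution(Q: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Stationary law pi with pi Q = 0, for an irreducible chain.

    Irreducibility (every combined state reachable from every other through
    positive rates) is checked first; otherwise the stationary law would
    ignore transient states, so a :class:`ReducibleChainError` is raised.
    The law itself is the null space of Q^T.
    """
    if not _strongly_connected(Q):
        raise ReducibleChainError(
            "generator is reducible (some combined state unreachable); "
            "use RootPrior(kind='uniform') or a fixed root prior"
        )
    _, s, Vt = np.linalg.svd(Q.T)
    pi = Vt[-1]
    pi = np.abs(pi.real)
    pi = pi / pi.sum()
    if pi.min() < -tol:
        raise ReducibleChainError("stationary solve produced negative mass")
    return pi
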