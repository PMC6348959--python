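"""Tip-data likelihood on a rooted tree: pruning engine and brute-force oracle.

The likelihood of the two binary characters is computed over the four
combined states with Felsenstein's pruning algorithm: tip partials are
indicator vectors (missing observations are all-ones), internal partials
combine children through the branch transition matrices, and the root
partial is dotted with the root prior.  Per-node rescaling keeps partials
in range on deep trees.

``brute_force_loglik`` sums over every assignment of states to internal
nodes (4^k terms) and serves as the exact reference for small trees.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .ctmc import (DependentRates, IndependentRates, build_Q,
                   stationary_distribution, transition_matrices)
from .phylo import PhyloTree, TreeIndex
from .traits import MISSING, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "RootPrior",
    "PruningEngine",
    "pruned_loglik",
    "brute_force_loglik",
    "binary_pruned_loglik",
]

# Combined-state composition: state index -> (habitat, leaf)
_STATE_BITS = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])


@dataclass(frozen=True)
class RootPrior:
    """Distribution over the four combined states at the root.

    kind='uniform' (default 1/4 each), 'stationary' (solved from the fitted
    generator; requires irreducibility), or 'fixed' with an explicit
    probability 4-vector.
    """

    kind: str = "uniform"
    probs: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "stationary", "fixed"):
            raise ValueError(f"unknown root prior kind {self.kind!r}")
        if self.kind == "fixed":
            p = np.asarray(self.probs, dtype=float)
            if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                raise ValueError("fixed root prior must be a probability 4-vector")
        elif self.probs is not None:
            raise ValueError("probs only valid with kind='fixed'")

    def vector(self, Q: np.ndarray | None = None) -> np.ndarray:
        if self.kind == "uniform":
            return np.full(4, 0.25)
        if self.kind == "fixed":
            return np.asarray(self.probs, dtype=float)
        if Q is None:
            raise ValueError("stationary root prior needs the generator")
        return stationary_distribution(Q)


def tip_partial(habitat: int, leaf: int) -> np.ndarray:
    """Indicator over combined states consistent with the (possibly missing) observation."""
    ok = np.ones(4)
    if habitat != MISSING:
        ok *= (_STATE_BITS[:, 0] == habitat).astype(float)
    if leaf != MISSING:
        ok *= (_STATE_BITS[:, 1] == leaf).astype(float)
    return ok


def _prune_kernel_py(parent, edge_P, partials, root):
    """Post-order accumulation; nodes are numbered in post-order already."""
    logscale = 0.0
    n = parent.shape[0]
    for i in range(n - 1):           # all non-root nodes precede the root
        m = partials[i].max()
        if m <= 0.0:
            return -np.inf
        partials[i] /= m
        logscale += np.log(m)
        partials[parent[i]] *= edge_P[i] @ partials[i]
    lik = partials[root]
    m = lik.max()
    if m <= 0.0:
        return -np.inf
    return logscale + np.log(m), lik / m


try:  # optional JIT of the inner loop; identical arithmetic
    import numba

    @numba.njit(cache=False, fastmath=False)
    def _prune_kernel_nb(parent, edge_P, partials, root):  # pragma: no cover
        logscale = 0.0
        n = parent.shape[0]
        for i in range(n - 1):
            m = 0.0
            for s in range(4):
                if partials[i, s] > m:
                    m = partials[i, s]
            if m <= 0.0:
                return -np.inf, partials[root]
            for s in range(4):
                partials[i, s] /= m
            logscale += np.log(m)
            p = parent[i]
            for s in range(4):
                acc = 0.0
                for t in range(4):
                    acc += edge_P[i, s, t] * partials[i, t]
                partials[p, s] *= acc
        m = 0.0
        for s in range(4):
            if partials[root, s] > m:
                m = partials[root, s]
        if m <= 0.0:
            return -np.inf, partials[root]
        return logscale + np.log(m), partials[root] / m

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


class PruningEngine:
    """Reusable pruning likelihood for one (tree, trait table) pair.

    Precomputes the post-order index and tip partials once, so repeated
    evaluations during optimization or MCMC only rebuild the generator and
    the per-branch transition matrices.
    """

    def __init__(self, tree: PhyloTree, traits: TraitTable,
                 root_prior: RootPrior = RootPrior()):
        self.idx: TreeIndex = tree.index()
        self.root_prior = root_prior
        absent = [l for l in self.idx.tip_label_to_id if l not in set(traits.taxa)]
        if absent:
            raise ValueError(f"tips absent from trait table: {sorted(absent)}")
        self._base = np.ones((self.idx.n_nodes, 4))
        for label, i in self.idx.tip_label_to_id.items():
            h, l = traits.states(label)
            self._base[i] = tip_partial(h, l)
        if any((self._base[i] == 0).all() for i in self.idx.tip_label_to_id.values()):
            raise ValueError("a tip has an impossible observation")
        self._kernel = _prune_kernel_nb if _HAVE_NUMBA else _prune_kernel_py

    def loglik(self, rates: DependentRates | IndependentRates) -> float:
        Q = build_Q(rates)
        P = transition_matrices(Q, self.idx.edge_length)
        partials = self._base.copy()
        out = self._kernel(self.idx.parent, P, partials, self.idx.root)
        if isinstance(out, float):  # python fallback signalled -inf
            return -np.inf
        logscale, rootlik = out
        if not np.isfinite(logscale):
            return -np.inf
        prior = self.root_prior.vector(Q)
        total = float(prior @ rootlik)
        if total <= 0.0:
            logger.warning("zero likelihood (conflicting tips on zero-length branches)")
            return -np.inf
        return logscale + float(np.log(total))


def pruned_loglik(tree: PhyloTree, traits: TraitTable,
                  rates: DependentRates | IndependentRates,
                  root_prior: RootPrior = RootPrior()) -> float:
    """Natural-log likelihood of the tip data under the model (pruning algorithm)."""
    return PruningEngine(tree, traits, root_prior).loglik(rates)


def brute_force_loglik(tree: PhyloTree, traits: TraitTable,
                       rates: DependentRates | IndependentRates,
                       root_prior: RootPrior = RootPrior(),
                       max_internal: int = 8) -> float:
    """Exact likelihood by enumerating internal-node state assignments.

    Exponential in the number of internal nodes (4^k terms); refuses more
    than ``max_internal`` and exists purely as an independent oracle.
    """
    idx = tree.index()
    internal = [i for i in range(idx.n_nodes) if not idx.is_tip[i]]
    if len(internal) > max_internal:
        raise ValueError(
            f"{len(internal)} internal nodes exceeds enumeration limit {max_internal}; "
            "prune the tree first"
        )
    Q = build_Q(rates)
    P = transition_matrices(Q, idx.edge_length)
    prior = root_prior.vector(Q)

    tipstate: dict[int, np.ndarray] = {}
    for label, i in idx.tip_label_to_id.items():
        h, l = traits.states(label)
        tipstate[i] = tip_partial(h, l)

    if idx.is_tip[idx.root]:  # single-tip tree: no internal nodes at all
        return float(np.log(prior @ tipstate[idx.root]))

    pos = {node: k for k, node in enumerate(internal)}
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        term = prior[assign[pos[idx.root]]]
        for i in range(idx.n_nodes):
            p = idx.parent[i]
            if p < 0:
                continue
            sp = assign[pos[p]]
            if idx.is_tip[i]:
                term *= float(P[i][sp] @ tipstate[i])
            else:
                term *= P[i][sp, assign[pos[i]]]
            if term == 0.0:
                break
        total += term
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))


def binary_pruned_loglik(tree: PhyloTree, states: dict[str, int],
                         gain: float, loss: float,
                         prior: tuple[float, float] = (0.5, 0.5)) -> float:
    """Single-character 2-state pruning likelihood (closed-form P matrices).

    Used as the independent-factorization oracle: under the independent
    model the joint log-likelihood is the sum of the two per-trait 2-state
    log-likelihoods.
    """
    idx = tree.index()
    r = gain + loss
    partials = np.ones((idx.n_nodes, 2))
    for label, i in idx.tip_label_to_id.items():
        s = states[label]
        if s != MISSING:
            partials[i] = np.eye(2)[s]
    logscale = 0.0
    for i in range(idx.n_nodes - 1):
        t = idx.edge_length[i]
        if r > 0:
            e = np.exp(-r * t)
            pi0, pi1 = loss / r, gain / r
            P = np.array([[pi0 + pi1 * e, pi1 * (1 - e)],
                          [pi0 * (1 - e), pi1 + pi0 * e]])
        else:
            P = np.eye(2)
        m = partials[i].max()
        if m <= 0:
            return -np.inf
        partials[i] /= m
        logscale += np.log(m)
        partials[idx.parent[i]] *= P @ partials[i]
    total = float(np.asarray(prior) @ partials[idx.root])
    if total <= 0:
        return -np.inf
    return logscale + float(np.log(total))
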