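"""Synthetic data with known ground truth: Yule trees, correlated binary
traits, and specimen-level leaf measurements.

Trait evolution is simulated by *endpoint sampling*: the root state is
drawn (or fixed) and each child's combined state is drawn from the row of
P(branch) = exp(Q branch) for its parent's state.  Only tip states are
observed downstream, so sampling transition endpoints is exact and no path
simulation is needed.

Leaf measurements emulate the herbarium protocol: 3 leaves per specimen,
10 specimens per species.  Lengths are log-normal around 80 mm; each
width is the length times a log-normal width/length ratio centred at 0.08
for "narrowly lanceolate" species (state 1) and 0.30 for wide-leaved ones
(state 0), with specimen- and leaf-level multiplicative noise.  The two
classes sit well on either side of the 0.15 coding threshold, as the real
measurement distributions do.

Named scenarios bracket the study conditions (50-300 tips around the ~50
taxon reduced tree): ``independent_null``, ``dependent_strong``,
``preadaptation`` (q24 = 10 q13, leaf change preceding habitat change),
and ``tiny_oracle`` (5 tips, enumerable by the brute-force likelihood).
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .ctmc import (DependentRates, IndependentRates, build_Q,
                   expand_independent, transition_matrices)
from .likelihood import RootPrior
from .phylo import PhyloTree, write_newick
from .traits import LeafMeasurementSet, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementParams", "Scenario", "SCENARIOS",
    "simulate_yule_tree", "simulate_traits", "simulate_measurements",
    "make_fixture",
]

_STATE_BITS = ((0, 0), (0, 1), (1, 0), (1, 1))


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree grown to ``n_tips``, ultrametric, tips t1..tn.

    After the n-th birth the terminal branches are extended by one
    Exp(n*birth_rate) holding time, so the youngest cherry does not sit at
    zero height.  Deterministic given the seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = random.Random(int(seed))
    dtree = birthdeath.birth_death_tree(
        birth_rate=float(birth_rate), death_rate=0.0,
        num_extant_tips=int(n_tips), rng=rng,
    )
    extra = rng.expovariate(n_tips * birth_rate)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # deterministic fresh labels in leaf order
    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(f"t{i}")
    dtree.taxon_namespace = ns
    dtree.seed_node.edge.length = None
    return PhyloTree(dtree)


def simulate_traits(tree: PhyloTree,
                    rates: DependentRates | IndependentRates,
                    root: int | RootPrior = RootPrior(),
                    seed: int = 0) -> TraitTable:
    """Forward-simulate the two binary characters down the tree.

    ``root`` is a fixed combined state in {1,2,3,4} or a RootPrior to draw
    from.  Children are visited in input order, so output is deterministic
    given the seed.
    """
    rng = np.random.default_rng([int(seed), 0x7A17])
    Q = build_Q(rates)
    idx = tree.index()
    P = transition_matrices(Q, idx.edge_length)
    if isinstance(root, RootPrior):
        prior = root.vector(Q)
        root_state = int(rng.choice(4, p=prior))
    else:
        if root not in (1, 2, 3, 4):
            raise ValueError("fixed root state must be in {1,2,3,4}")
        root_state = int(root) - 1

    state = np.empty(idx.n_nodes, dtype=np.int64)
    state[idx.root] = root_state
    # parent ids are always larger than child ids (post-order numbering),
    # so a reversed sweep visits parents first
    for i in range(idx.n_nodes - 2, -1, -1):
        row = P[i][state[idx.parent[i]]]
        row = row / row.sum()
        state[i] = rng.choice(4, p=row)

    rows = {}
    for label, i in sorted(idx.tip_label_to_id.items(), key=lambda kv: kv[1]):
        h, l = _STATE_BITS[state[i]]
        rows[label] = (h, l)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["habitat_state", "leaf_state"])
    df.index.name = "taxon"
    return TraitTable(df)


@dataclass(frozen=True)
class MeasurementParams:
    """Log-normal leaf-geometry parameters (ratios dimensionless, lengths mm)."""

    ratio_state1: float = 0.08   # width/length centre, narrowly lanceolate
    ratio_state0: float = 0.30   # width/length centre, wide leaves
    ratio_leaf_sd: float = 0.20  # leaf-level log-sd of the ratio
    ratio_specimen_sd: float = 0.10  # specimen-level log-sd
    length_mean_mm: float = 80.0
    length_sd: float = 0.30      # log-sd of leaf length
    n_specimens: int = 10
    n_leaves: int = 3

    def __post_init__(self) -> None:
        if min(self.ratio_state1, self.ratio_state0, self.length_mean_mm) <= 0:
            raise ValueError("measurement location parameters must be positive")
        if min(self.ratio_leaf_sd, self.ratio_specimen_sd, self.length_sd) <= 0:
            raise ValueError("measurement spreads must be positive")


def simulate_measurements(states: dict[str, int],
                          params: MeasurementParams = MeasurementParams(),
                          seed: int = 0) -> LeafMeasurementSet:
    """Specimen-level measurements whose coded index recovers each species' state."""
    rng = np.random.default_rng([int(seed), 0x1EAF])
    recs = []
    for species in states:  # dict order = caller order, deterministic
        centre = params.ratio_state1 if states[species] == 1 else params.ratio_state0
        for sp in range(1, params.n_specimens + 1):
            specimen_ratio = centre * np.exp(rng.normal(0, params.ratio_specimen_sd))
            for leaf in range(1, params.n_leaves + 1):
                length = params.length_mean_mm * np.exp(rng.normal(0, params.length_sd))
                ratio = specimen_ratio * np.exp(rng.normal(0, params.ratio_leaf_sd))
                recs.append((species, f"{species}_s{sp:02d}", leaf,
                             round(length, 3), round(length * ratio, 3)))
    df = pd.DataFrame(recs, columns=["species", "specimen_id", "leaf_id",
                                     "length_mm", "width_mm"])
    return LeafMeasurementSet(df)


@dataclass(frozen=True)
class Scenario:
    """A named simulation condition with full ground truth."""

    name: str
    n_tips: int
    birth_rate: float
    rates: DependentRates | IndependentRates
    root_state: int                 # combined state 1..4
    measurement: MeasurementParams = MeasurementParams()
    seed: int = 20230415

    def truth(self) -> dict:
        return {
            "name": self.name,
            "n_tips": self.n_tips,
            "birth_rate": self.birth_rate,
            "model": "independent" if isinstance(self.rates, IndependentRates)
                     else "dependent",
            "rates": self.rates.as_dict(),
            "expanded_rates": expand_independent(self.rates).as_dict()
            if isinstance(self.rates, IndependentRates) else self.rates.as_dict(),
            "root_state": self.root_state,
            "measurement": asdict(self.measurement),
            "seed": self.seed,
        }


# Rates are events per unit branch length on trees of total length ~ n_tips
# (Yule, birth rate 1), so 0.05-0.5 gives a handful to dozens of expected
# changes — informative without saturation.
SCENARIOS: dict[str, Scenario] = {
    "independent_null": Scenario(
        name="independent_null", n_tips=100, birth_rate=1.0,
        rates=IndependentRates(alpha1=0.1, beta1=0.1, alpha2=0.1, beta2=0.1),
        root_state=1,
    ),
    "dependent_strong": Scenario(
        name="dependent_strong", n_tips=300, birth_rate=1.0,
        rates=DependentRates(q12=0.15, q13=0.05, q21=0.15, q24=0.5,
                             q31=0.1, q34=0.3, q42=0.1, q43=0.1),
        root_state=1,
    ),
    "preadaptation": Scenario(
        name="preadaptation", n_tips=300, birth_rate=1.0,
        # leaf change first (large q12), then habitat shift in narrow-leaved
        # lineages (large q24); direct habitat shift rare (q24 = 10 q13)
        rates=DependentRates(q12=0.4, q13=0.05, q21=0.15, q24=0.5,
                             q31=0.1, q34=0.15, q42=0.1, q43=0.1),
        root_state=1,
    ),
    "tiny_oracle": Scenario(
        name="tiny_oracle", n_tips=5, birth_rate=1.0,
        rates=DependentRates(q12=0.3, q13=0.3, q21=0.3, q24=0.3,
                             q31=0.3, q34=0.3, q42=0.3, q43=0.3),
        root_state=1,
    ),
}


def make_fixture(scenario: str, out_dir, n_tips: int | None = None,
                 seed: int | None = None) -> dict:
    """Write a fixture bundle (tree + traits + measurements + truth JSON).

    Bundles regenerate bit-identically from the seed embedded in the truth
    file.  Returns the truth dict with the written paths added.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; options: {sorted(SCENARIOS)}")
    sc = SCENARIOS[scenario]
    if n_tips is not None or seed is not None:
        sc = Scenario(name=sc.name, n_tips=n_tips or sc.n_tips,
                      birth_rate=sc.birth_rate, rates=sc.rates,
                      root_state=sc.root_state, measurement=sc.measurement,
                      seed=sc.seed if seed is None else int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = simulate_yule_tree(sc.n_tips, sc.birth_rate, sc.seed)
    traits = simulate_traits(tree, sc.rates, root=sc.root_state, seed=sc.seed + 1)
    meas = simulate_measurements(traits.character("leaf"), sc.measurement,
                                 seed=sc.seed + 2)

    paths = {
        "tree": out / f"{sc.name}.nwk",
        "traits": out / f"{sc.name}_traits.csv",
        "measurements": out / f"{sc.name}_measurements.csv",
        "truth": out / f"{sc.name}_truth.json",
    }
    paths["tree"].write_text(write_newick(tree) + "\n", encoding="utf-8")
    df = traits.data.copy()
    df.index.name = "taxon"
    df.to_csv(paths["traits"])
    meas.to_csv(paths["measurements"])
    truth = sc.truth()
    truth["files"] = {k: str(v) for k, v in paths.items()}
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n", encoding="utf-8")
    logger.info("fixture %s written to %s", sc.name, out)
    return truth
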