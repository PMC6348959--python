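"""Synthetic-data generator: trees, traits, measurements, fixtures."""

import json

import numpy as np
import pytest

from traitlink.ctmc import DependentRates, IndependentRates, build_Q, stationary_distribution
from traitlink.phylo import parse_newick
from traitlink.simulate import (SCENARIOS, MeasurementParams, make_fixture,
                                simulate_measurements, simulate_traits,
                                simulate_yule_tree)
from traitlink.traits import binarize_leaf, leaf_shape_index


def test_yule_tree_shape_and_determinism():
    t = simulate_yule_tree(50, 1.0, seed=9)
    assert t.n_tips == 50
    assert t.n_internal == 49  # strictly binary
    assert sorted(t.tip_labels, key=lambda s: int(s[1:])) == [f"t{i}" for i in range(1, 51)]
    t2 = simulate_yule_tree(50, 1.0, seed=9)
    from traitlink.phylo import write_newick

    assert write_newick(t) == write_newick(t2)
    with pytest.raises(ValueError):
        simulate_yule_tree(1, 1.0, 0)
    with pytest.raises(ValueError):
        simulate_yule_tree(5, -1.0, 0)


def test_yule_tree_is_ultrametric():
    t = simulate_yule_tree(40, 2.0, seed=3)
    depths = [lf.distance_from_root() for lf in t.dtree.leaf_node_iter()]
    assert max(depths) - min(depths) < 1e-9


def test_yule_interval_law():
    # while k lineages exist the next speciation waits Exp(k*lambda), so
    # k * interval_k has unit mean at lambda = 1; checked over 200 trees
    lam, n = 1.0, 12
    scaled = []
    for seed in range(200):
        t = simulate_yule_tree(n, lam, seed=seed)
        ages = sorted(nd.distance_from_root() for nd in t.dtree.preorder_node_iter()
                      if not nd.is_leaf())
        height = max(lf.distance_from_root() for lf in t.dtree.leaf_node_iter())
        times = ages + [height]
        for k in range(1, len(times)):
            scaled.append((k + 1) * (times[k] - times[k - 1]) * lam)
    m = np.mean(scaled)
    se = np.std(scaled) / np.sqrt(len(scaled))
    assert abs(m - 1.0) < 3 * se + 0.05


def test_traits_zero_branches_copy_root():
    tree = parse_newick("(A:0.0,B:0.0,C:0.0);")
    r = DependentRates(*[5.0] * 8)
    traits = simulate_traits(tree, r, root=3, seed=1)
    assert all(traits.states(l) == (1, 0) for l in "ABC")


def test_traits_deterministic_and_paired():
    tree = simulate_yule_tree(30, 1.0, 5)
    r = SCENARIOS["dependent_strong"].rates
    a = simulate_traits(tree, r, root=1, seed=77)
    b = simulate_traits(tree, r, root=1, seed=77)
    assert a.data.equals(b.data)
    assert set(a.taxa) == set(tree.tip_labels)


def test_star_tree_reaches_stationary_law():
    n = 1000
    newick = "(" + ",".join(f"t{i}:100.0" for i in range(n)) + ");"
    tree = parse_newick(newick)
    r = DependentRates(*[1.0] * 8)
    traits = simulate_traits(tree, r, root=1, seed=8)
    pi = stationary_distribution(build_Q(r))  # uniform by symmetry
    counts = np.zeros(4)
    code = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}
    for l in tree.tip_labels:
        counts[code[traits.states(l)]] += 1
    freq = counts / n
    se = np.sqrt(pi * (1 - pi) / n)
    assert np.all(np.abs(freq - pi) < 3 * se + 1e-3)


def test_independent_rates_give_uncorrelated_characters():
    rates = IndependentRates(0.3, 0.3, 0.3, 0.3)
    tree = simulate_yule_tree(50, 1.0, 123)
    corrs = []
    for rep in range(200):
        traits = simulate_traits(tree, rates, root=1, seed=rep)
        h = traits.data["habitat_state"].to_numpy(float)
        l = traits.data["leaf_state"].to_numpy(float)
        if h.std() > 0 and l.std() > 0:
            corrs.append(np.corrcoef(h, l)[0, 1])
    m = np.mean(corrs)
    se = np.std(corrs) / np.sqrt(len(corrs))
    assert abs(m) < 2 * se + 0.02


def test_measurement_protocol_and_recovery():
    states = {f"s{i}": i % 2 for i in range(100)}
    meas = simulate_measurements(states, seed=4)
    counts = meas.records.groupby("species").size()
    assert (counts == 30).all()  # 3 leaves x 10 specimens
    ok = sum(binarize_leaf(leaf_shape_index(meas, sp)) == st
             for sp, st in states.items())
    assert ok >= 95
    again = simulate_measurements(states, seed=4)
    assert meas.records.equals(again.records)


def test_measurement_params_validated():
    with pytest.raises(ValueError):
        MeasurementParams(ratio_state1=-0.1)
    with pytest.raises(ValueError):
        MeasurementParams(ratio_leaf_sd=0.0)


def test_make_fixture_bundles(tmp_path):
    truth = make_fixture("tiny_oracle", tmp_path / "a")
    tree = parse_newick((tmp_path / "a" / "tiny_oracle.nwk").read_text())
    assert tree.n_tips == 5
    # regenerates bit-identically from the embedded seed
    make_fixture("tiny_oracle", tmp_path / "b", seed=truth["seed"])
    for name in ("tiny_oracle.nwk", "tiny_oracle_traits.csv",
                 "tiny_oracle_measurements.csv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    pre = SCENARIOS["preadaptation"]
    assert pre.rates.q24 / pre.rates.q13 == pytest.approx(10.0)
    with pytest.raises(ValueError, match="unknown scenario"):
        make_fixture("nope", tmp_path)


def test_fixture_truth_records_parameters(tmp_path):
    truth = make_fixture("tiny_oracle", tmp_path)
    loaded = json.loads((tmp_path / "tiny_oracle_truth.json").read_text())
    assert loaded["rates"] == truth["rates"]
    assert loaded["seed"] == truth["seed"]
    assert loaded["model"] == "dependent"
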