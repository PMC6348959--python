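"""Leaf-shape index, binarization, habitat coding, and trait CSV round trips."""

import numpy as np
import pandas as pd
import pytest

from traitlink.traits import (HABITAT_VOCABULARY, MISSING, LeafMeasurementSet,
                              TraitTable, binarize_leaf, build_trait_table,
                              code_habitat, leaf_shape_index, read_trait_table,
                              write_trait_table)


def measurements_from(rows):
    return LeafMeasurementSet(pd.DataFrame(
        rows, columns=["species", "specimen_id", "leaf_id", "length_mm", "width_mm"]))


def test_index_single_specimen_constant_ratio():
    m = measurements_from([
        ("sp", "s1", 1, 100, 10), ("sp", "s1", 2, 80, 8), ("sp", "s1", 3, 120, 12)])
    assert leaf_shape_index(m, "sp") == pytest.approx(0.10)


def test_index_is_mean_of_specimen_means():
    m = measurements_from([
        ("sp", "s1", 1, 100, 10), ("sp", "s2", 1, 100, 20)])
    assert leaf_shape_index(m, "sp") == pytest.approx(0.15)


def test_index_invariant_under_record_order():
    rows = [("sp", f"s{i}", j, 100 + 3 * i, 11 + i + j) for i in range(4) for j in (1, 2, 3)]
    m1 = measurements_from(rows)
    m2 = measurements_from(rows[::-1])
    assert leaf_shape_index(m1, "sp") == pytest.approx(leaf_shape_index(m2, "sp"), rel=1e-12)


def test_index_unknown_species_and_bad_measurements():
    m = measurements_from([("sp", "s1", 1, 100, 10)])
    with pytest.raises(ValueError, match="unknown species"):
        leaf_shape_index(m, "nope")
    with pytest.raises(ValueError, match="non-positive"):
        measurements_from([("sp", "s1", 1, 100, 0)])


def test_binarize_boundary_is_state_one():
    assert binarize_leaf(0.15) == 1      # the threshold itself counts as narrow
    assert binarize_leaf(0.1501) == 0
    assert binarize_leaf(0.08) == 1
    with pytest.raises(ValueError):
        binarize_leaf(0.0)


def test_binarize_monotone_single_breakpoint():
    grid = np.linspace(0.01, 0.5, 200)
    states = [binarize_leaf(v) for v in grid]
    assert all(a >= b for a, b in zip(states, states[1:]))
    flips = sum(a != b for a, b in zip(states, states[1:]))
    assert flips == 1


def test_code_habitat_definitions():
    assert code_habitat("stream_bank", "broad") == 1
    assert code_habitat("stream_bank", "narrow") == 1
    assert code_habitat("swamp_or_pool_margin", "broad") == 1
    assert code_habitat("swamp_or_pool_margin", "narrow") == 0
    assert code_habitat("dry", "broad") == 0
    assert code_habitat("dry", "narrow") == 0
    with pytest.raises(ValueError, match="unknown habitat"):
        code_habitat("lunar", "broad")


def test_narrow_riparian_subset_of_broad():
    for cat in HABITAT_VOCABULARY:
        assert code_habitat(cat, "narrow") <= code_habitat(cat, "broad")


def test_trait_table_validation():
    df = pd.DataFrame({"habitat_state": [0, 2], "leaf_state": [1, 0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="outside"):
        TraitTable(df)
    dup = pd.DataFrame({"habitat_state": [0, 1], "leaf_state": [1, 0]}, index=["a", "a"])
    with pytest.raises(ValueError, match="duplicate"):
        TraitTable(dup)


def test_csv_roundtrip(tmp_path):
    df = pd.DataFrame({"habitat_state": [0, 1, MISSING],
                       "leaf_state": [1, MISSING, 0]},
                      index=["a", "b", "c"])
    df.index.name = "taxon"
    t = TraitTable(df)
    p = tmp_path / "traits.csv"
    write_trait_table(t, p)
    back = read_trait_table(p)
    pd.testing.assert_frame_equal(
        back.data[["habitat_state", "leaf_state"]].astype(int),
        t.data.astype(int))


def test_read_from_categories_and_index(tmp_path):
    p = tmp_path / "raw.csv"
    p.write_text(
        "taxon,habitat_category,leaf_index\n"
        "a,stream_bank,0.08\n"
        "b,swamp_or_pool_margin,0.30\n"
        "c,dry,\n"
    )
    broad = read_trait_table(p, definition="broad")
    narrow = read_trait_table(p, definition="narrow")
    assert broad.states("a") == (1, 1)
    assert broad.states("b") == (1, 0)
    assert narrow.states("b") == (0, 0)
    assert narrow.states("c")[1] == MISSING


def test_build_trait_table_from_measurements():
    m = measurements_from([("a", "s1", 1, 100, 10), ("b", "s1", 1, 100, 40)])
    t = build_trait_table({"a": "stream_bank", "b": "dry", "c": "forest"},
                          "broad", measurements=m)
    assert t.states("a") == (1, 1)
    assert t.states("b") == (0, 0)
    assert t.states("c") == (0, MISSING)
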