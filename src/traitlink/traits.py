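"""Binary trait coding: leaf-shape index and riparian habitat.

Two binary characters drive the whole analysis:

* habitat — state 0 non-riparian, state 1 riparian, under either a *narrow*
  definition (only river/stream banks) or a *broad* one (also swamps, pool
  margins and other wet habitats);
* leaf shape — state 1 ("narrowly lanceolate") when the species leaf-shape
  index, the mean leaf width/length ratio, is at or below 0.15.

The index aggregates specimen-wise: per-leaf width/length ratios are
averaged within each specimen, then specimen means are averaged per
species.  A pooled per-leaf alternative is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "LEAF_INDEX_THRESHOLD",
    "HABITAT_VOCABULARY",
    "LeafMeasurementSet",
    "TraitTable",
    "leaf_shape_index",
    "binarize_leaf",
    "code_habitat",
    "build_trait_table",
    "read_trait_table",
    "write_trait_table",
]

MISSING = -1  # sentinel for an unobserved binary state
LEAF_INDEX_THRESHOLD = 0.15

# Controlled habitat vocabulary.  Narrow-sense riparian = stream banks only;
# broad-sense additionally counts the other wet categories.
_WET_CATEGORIES = frozenset({"stream_bank", "swamp_or_pool_margin", "other_wet"})
HABITAT_VOCABULARY = frozenset(
    {"stream_bank", "swamp_or_pool_margin", "other_wet", "dry", "forest", "alpine", "other_dry"}
)


@dataclass
class LeafMeasurementSet:
    """Specimen-level leaf measurements (length and width in mm).

    The intended design is 3 middle cauline leaves per specimen and 10
    specimens per species; deviations are allowed but logged.
    """

    records: pd.DataFrame  # columns: species, specimen_id, leaf_id, length_mm, width_mm

    REQUIRED = ("species", "specimen_id", "leaf_id", "length_mm", "width_mm")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table lacks columns: {missing}")
        if (df["length_mm"] <= 0).any() or (df["width_mm"] <= 0).any():
            bad = df[(df["length_mm"] <= 0) | (df["width_mm"] <= 0)]
            raise ValueError(
                f"non-positive leaf measurements for species: {sorted(bad['species'].unique())}"
            )
        counts = df.groupby("species").size()
        off_design = counts[counts != 30]
        if len(off_design):
            logger.info(
                "%d species deviate from the 3-leaves x 10-specimens design", len(off_design)
            )

    @classmethod
    def from_csv(cls, path) -> "LeafMeasurementSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())


def leaf_shape_index(measurements: LeafMeasurementSet, species: str,
                     pooled: bool = False) -> float:
    """Species leaf-shape index: mean width/length ratio.

    Default aggregation is specimen-wise (leaf ratios -> specimen mean ->
    species mean).  ``pooled=True`` averages all leaf ratios directly; the
    two differ only for unbalanced designs and the choice is logged then.
    """
    df = measurements.records
    sub = df[df["species"] == species]
    if sub.empty:
        raise ValueError(f"unknown species: {species!r}")
    ratios = sub["width_mm"] / sub["length_mm"]
    if pooled:
        return float(ratios.mean())
    per_specimen = ratios.groupby(sub["specimen_id"]).mean()
    if per_specimen.size and sub.groupby("specimen_id").size().nunique() > 1:
        logger.info("unbalanced leaf counts for %s; specimen-wise aggregation used", species)
    return float(per_specimen.mean())


def binarize_leaf(index: float, threshold: float = LEAF_INDEX_THRESHOLD) -> int:
    """1 ("narrowly lanceolate") iff index <= threshold; the boundary itself is state 1."""
    if not index > 0:
        raise ValueError(f"leaf-shape index must be positive, got {index}")
    return 1 if index <= threshold else 0


def code_habitat(category: str, definition: str) -> int:
    """Map a controlled habitat category to the binary riparian state.

    ``definition='narrow'``: state 1 only for ``stream_bank``.
    ``definition='broad'``: state 1 for any wet category.
    """
    if definition not in ("broad", "narrow"):
        raise ValueError(f"definition must be 'broad' or 'narrow', got {definition!r}")
    if category not in HABITAT_VOCABULARY:
        raise ValueError(
            f"unknown habitat category {category!r}; known: {sorted(HABITAT_VOCABULARY)}"
        )
    if definition == "narrow":
        return 1 if category == "stream_bank" else 0
    return 1 if category in _WET_CATEGORIES else 0


@dataclass
class TraitTable:
    """Per-taxon binary states: habitat and leaf shape, with optional index.

    ``habitat_state``/``leaf_state`` take values 0, 1 or ``MISSING`` (-1);
    missing states are treated as ambiguous (all states possible) in the
    likelihood.
    """

    data: pd.DataFrame  # index: taxon; columns: habitat_state, leaf_state, [leaf_index]
    habitat_definition: str = "broad"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate taxon rows: {dups}")
        for col in ("habitat_state", "leaf_state"):
            if col not in df.columns:
                raise ValueError(f"trait table lacks column {col!r}")
            bad = ~df[col].isin([0, 1, MISSING])
            if bad.any():
                raise ValueError(
                    f"states outside {{0,1,missing}} in {col}: taxa {sorted(df.index[bad])}"
                )
        n_missing = int((df[["habitat_state", "leaf_state"]] == MISSING).sum().sum())
        if n_missing:
            logger.info("%d missing trait cells coded as ambiguous", n_missing)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def states(self, taxon: str) -> tuple[int, int]:
        row = self.data.loc[taxon]
        return int(row["habitat_state"]), int(row["leaf_state"])

    def character(self, which: str) -> dict[str, int]:
        """One binary character as a taxon -> state map (may contain MISSING)."""
        col = {"habitat": "habitat_state", "leaf": "leaf_state"}[which]
        return {t: int(v) for t, v in self.data[col].items()}

    def subset(self, taxa) -> "TraitTable":
        return TraitTable(self.data.loc[list(taxa)].copy(), self.habitat_definition)


def build_trait_table(
    habitat_categories: dict[str, str],
    definition: str,
    measurements: LeafMeasurementSet | None = None,
    leaf_indices: dict[str, float] | None = None,
    threshold: float = LEAF_INDEX_THRESHOLD,
) -> TraitTable:
    """Assemble a TraitTable from habitat categories plus either raw
    measurements or precomputed leaf-shape indices."""
    if (measurements is None) == (leaf_indices is None):
        raise ValueError("provide exactly one of measurements or leaf_indices")
    if leaf_indices is None:
        leaf_indices = {
            sp: leaf_shape_index(measurements, sp) for sp in measurements.species
        }
    rows = {}
    for taxon, cat in habitat_categories.items():
        hab = code_habitat(cat, definition)
        if taxon in leaf_indices:
            idx = leaf_indices[taxon]
            rows[taxon] = (hab, binarize_leaf(idx, threshold), idx)
        else:
            logger.info("no leaf data for %s; leaf state coded missing", taxon)
            rows[taxon] = (hab, MISSING, np.nan)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["habitat_state", "leaf_state", "leaf_index"]
    )
    df.index.name = "taxon"
    return TraitTable(df, definition)


def read_trait_table(path, definition: str = "broad",
                     threshold: float = LEAF_INDEX_THRESHOLD) -> TraitTable:
    """Read a trait CSV.

    Accepted columns: ``taxon`` plus ``habitat_state`` or
    ``habitat_category``, and ``leaf_state`` or ``leaf_index``.  Empty cells
    become the missing state (count logged).
    """
    df = pd.read_csv(path, dtype={"taxon": str})
    if "taxon" not in df.columns:
        raise ValueError("trait CSV requires a 'taxon' column")
    df = df.set_index("taxon")

    if "habitat_state" in df.columns:
        hab = df["habitat_state"]
    elif "habitat_category" in df.columns:
        hab = df["habitat_category"].map(
            lambda c: MISSING if pd.isna(c) else code_habitat(str(c), definition)
        )
    else:
        raise ValueError("trait CSV requires habitat_state or habitat_category")

    out = pd.DataFrame(index=df.index)
    out["habitat_state"] = _coerce_state(hab)
    if "leaf_state" in df.columns:
        out["leaf_state"] = _coerce_state(df["leaf_state"])
        if "leaf_index" in df.columns:
            out["leaf_index"] = df["leaf_index"]
    elif "leaf_index" in df.columns:
        out["leaf_state"] = df["leaf_index"].map(
            lambda v: MISSING if pd.isna(v) else binarize_leaf(float(v), threshold)
        )
        out["leaf_index"] = df["leaf_index"]
    else:
        raise ValueError("trait CSV requires leaf_state or leaf_index")
    return TraitTable(out, definition)


def write_trait_table(table: TraitTable, path) -> None:
    df = table.data.copy()
    df.index.name = "taxon"
    df.to_csv(path)


def _coerce_state(series: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v):
            return MISSING
        iv = int(v)
        if iv not in (0, 1, MISSING):
            raise ValueError(f"state outside {{0,1}}: {v!r}")
        return iv

    return series.map(one).astype(np.int64)
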