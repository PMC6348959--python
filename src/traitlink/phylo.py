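"""Rooted phylogenies: Newick I/O, pruning, and flat traversal indexing.

The package consumes a rooted tree with branch lengths in arbitrary time
units; it never infers one.  Trees are held as :class:`PhyloTree`, a thin
validated wrapper around a :class:`dendropy.Tree`.  Children are kept in
input order so every traversal is deterministic; polytomies are permitted;
zero-length branches are legal (their transition matrix is the identity).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "TreeIndex",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "prune_to_taxa",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or violates tree invariants."""


@dataclass
class PhyloTree:
    """A rooted phylogeny with named tips and non-negative branch lengths.

    Wraps a :class:`dendropy.Tree`; use :func:`parse_newick` /
    :func:`write_newick` for I/O.  If the input has a basal trifurcation it
    is treated as rooted at that node (a warning is logged), mirroring
    analyses where the root is fixed externally.
    """

    dtree: dendropy.Tree

    def __post_init__(self) -> None:
        self._validate()

    # -- invariant checks -------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.dtree.leaf_node_iter():
            label = _tip_label(leaf)
            if not label:
                raise NewickParseError("tree contains an unlabelled tip")
            if label in seen:
                raise NewickParseError(f"duplicate tip label: {label!r}")
            seen.add(label)
        if not seen:
            raise NewickParseError("tree has no tips")
        n_defaulted = 0
        for node in self.dtree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                node.edge.length = 0.0
                n_defaulted += 1
            elif node.edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {node.edge.length} at {_tip_label(node) or 'internal node'}"
                )
        if n_defaulted:
            logger.warning("%d branch lengths absent; defaulted to 0", n_defaulted)
        root = self.dtree.seed_node
        if len(root.child_nodes()) > 2:
            logger.warning(
                "root is a polytomy (degree %d); treating the tree as rooted there",
                len(root.child_nodes()),
            )

    # -- basic properties -------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in deterministic (input) leaf order."""
        return [_tip_label(lf) for lf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self.dtree.preorder_node_iter() if not n.is_leaf())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.dtree.clone(depth=1))

    def index(self) -> "TreeIndex":
        return TreeIndex.from_tree(self)

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self.dtree.phylogenetic_distance_matrix()
        ta = self.dtree.taxon_namespace.get_taxon(a)
        tb = self.dtree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)


@dataclass
class TreeIndex:
    """Flat arrays for fast deterministic post-order computation.

    Node ids are assigned in post-order (children in input order), so
    ``order`` is simply 0..n_nodes-1 and the root is the last id.  Tips are
    the ids with no children; ``tip_label_to_id`` maps taxon names to ids.
    """

    parent: np.ndarray          # (n_nodes,) int; -1 for root
    edge_length: np.ndarray     # (n_nodes,) float; 0.0 for root
    is_tip: np.ndarray          # (n_nodes,) bool
    tip_label_to_id: dict[str, int]
    root: int

    @classmethod
    def from_tree(cls, tree: PhyloTree) -> "TreeIndex":
        nodes = list(tree.dtree.postorder_node_iter())
        ids = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        edge = np.zeros(n, dtype=np.float64)
        tip = np.zeros(n, dtype=bool)
        labels: dict[str, int] = {}
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                parent[i] = ids[id(node.parent_node)]
                edge[i] = float(node.edge.length or 0.0)
            if node.is_leaf():
                tip[i] = True
                labels[_tip_label(node)] = i
        return cls(parent=parent, edge_length=edge, is_tip=tip,
                   tip_label_to_id=labels, root=n - 1)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out


def _tip_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label is not None:
        return str(node.taxon.label)
    return str(node.label) if node.label is not None else None


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement.

    Bare-label underscores are kept verbatim (no conversion to spaces) and
    single-quoted labels are accepted, so taxon names match the trait table
    exactly.  Missing branch lengths default to 0 with a logged warning.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    if ";" not in text:
        raise NewickParseError("Newick statement must be terminated by ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failed: {exc}") from exc
    return PhyloTree(dtree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize to a single Newick line with 10-significant-digit lengths."""
    buf = io.StringIO()
    tree.dtree.write(
        file=buf,
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    return buf.getvalue().strip()


def read_newick_file(path) -> PhyloTree:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def prune_to_taxa(tree: PhyloTree, keep) -> PhyloTree:
    """Restrict the tree to ``keep``, suppressing unlabelled degree-2 nodes.

    Collapsed branch lengths are summed, so patristic distances between the
    kept tips are preserved exactly.  Unknown taxa raise a ``ValueError``
    naming every offender.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must be a non-empty set of tip labels")
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise ValueError(f"taxa not in tree: {', '.join(missing)}")
    if keep == have:
        return tree.copy()
    dtree = tree.dtree.clone(depth=1)
    dtree.retain_taxa_with_labels(sorted(keep))
    # dendropy may leave the old root as an unlabelled unifurcation chain;
    # re-seat at the first node with >=2 children (the MRCA of keep).
    node = dtree.seed_node
    while len(node.child_nodes()) == 1 and len(keep) > 1:
        node = node.child_nodes()[0]
    if node is not dtree.seed_node:
        node.parent_node = None
        dtree.seed_node = node
    return PhyloTree(dtree)
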