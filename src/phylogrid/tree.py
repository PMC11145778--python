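"""Rooted phylogenies with branch lengths.

A :class:`Phylogeny` is the shared currency of the package: the phylogenetic
tree proper for PD/NRI/PE and, with clustering heights as branch lengths, the
trait dendrogram for FD/NFRI/FE.  It is a lightweight array-backed structure
(parent pointers + edge lengths) with cached tip/branch incidence used by the
diversity and endemism computations; dendropy does the Newick parsing.
"""

from __future__ import annotations

import io
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "NewickParseError", "read_newick", "write_newick"]


class NewickParseError(ValueError):
    """Raised when a Newick file violates the format or tree invariants."""


class Phylogeny:
    """A rooted tree with nonnegative branch lengths and uniquely labelled tips.

    Parameters
    ----------
    parent
        ``parent[i]`` is the index of node *i*'s parent; the single root has
        parent ``-1``.  Nodes must be topologically ordered (parent before
        child is *not* required; any order is accepted).
    length
        Branch length of the edge above each node; the root's entry is
        ignored (treated as 0).
    tip_labels
        Mapping from node index to label for leaf nodes, given as a dict.
    """

    def __init__(self, parent: Sequence[int], length: Sequence[float], tip_labels: dict[int, str]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.float64).copy()
        n = self.parent.size
        if self.length.size != n:
            raise ValueError("parent and length must have equal size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise NewickParseError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.length[self.root] = 0.0
        if np.any(self.length < 0):
            bad = int(np.flatnonzero(self.length < 0)[0])
            raise NewickParseError(f"negative branch length {self.length[bad]} at node {bad}")
        # children lists
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self._children[self.parent[i]].append(i)
        leaves = [i for i in range(n) if not self._children[i]]
        if set(tip_labels) != set(leaves):
            raise ValueError("tip_labels must label exactly the leaf nodes")
        labels = [tip_labels[i] for i in leaves]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate tip label(s): {', '.join(dup)}")
        self._tip_nodes = np.asarray(leaves, dtype=np.int64)
        self._node_label = dict(tip_labels)
        # caches
        self._B: np.ndarray | None = None
        self._D: np.ndarray | None = None

    # ------------------------------------------------------------------ basics

    @property
    def n_tips(self) -> int:
        return self._tip_nodes.size

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in node order (stable for a given construction)."""
        return [self._node_label[i] for i in self._tip_nodes]

    def total_branch_length(self) -> float:
        """Sum of all branch lengths (the root carries no branch)."""
        return float(self.length.sum())

    def tip_index(self, labels: Sequence[str]) -> np.ndarray:
        """Positions of ``labels`` within :attr:`tip_labels`; unknown labels raise."""
        lookup = {l: k for k, l in enumerate(self.tip_labels)}
        missing = [l for l in labels if l not in lookup]
        if missing:
            raise KeyError(f"species not in tree: {', '.join(sorted(missing))}")
        return np.asarray([lookup[l] for l in labels], dtype=np.int64)

    # ------------------------------------------------------- incidence caches

    @property
    def branch_tip_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: entry (b, t) true iff tip *t*
        descends through the edge above node *b*.  The root row is all-False
        (there is no edge above the root)."""
        if self._B is None:
            n = self.parent.size
            B = np.zeros((n, self.n_tips), dtype=bool)
            for k, node in enumerate(self._tip_nodes):
                i = int(node)
                while i != self.root:
                    B[i, k] = True
                    i = int(self.parent[i])
            B[self.root, :] = False
            self._B = B
        return self._B

    @property
    def patristic_matrix(self) -> np.ndarray:
        """Dense (n_tips, n_tips) matrix of path-length distances between tips."""
        if self._D is None:
            B = self.branch_tip_matrix.astype(np.float64)
            W = self.length[:, None] * B
            shared = B.T @ W              # shared path length to root
            depth = np.diag(shared)
            self._D = depth[:, None] + depth[None, :] - 2.0 * shared
            np.fill_diagonal(self._D, 0.0)
        return self._D

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        B = self.branch_tip_matrix
        depths = self.length @ B
        return bool(np.allclose(depths, depths[0], rtol=rtol, atol=1e-12))

    # ------------------------------------------------------------------ output

    def to_newick(self, precision: int = 10) -> str:
        """Canonical Newick string: children ordered lexicographically by their
        smallest descendant tip label, branch lengths at ``precision``
        significant digits."""
        min_tip: dict[int, str] = {}

        def smallest(i: int) -> str:
            if i not in min_tip:
                if not self._children[i]:
                    min_tip[i] = self._node_label[i]
                else:
                    min_tip[i] = min(smallest(c) for c in self._children[i])
            return min_tip[i]

        out = io.StringIO()

        def emit(i: int) -> None:
            kids = sorted(self._children[i], key=smallest)
            if kids:
                out.write("(")
                for j, c in enumerate(kids):
                    if j:
                        out.write(",")
                    emit(c)
                out.write(")")
            else:
                out.write(self._node_label[i])
            if i != self.root:
                out.write(":" + format(self.length[i], f".{precision}g"))

        emit(self.root)
        out.write(";")
        return out.getvalue()

    # ----------------------------------------------------------------- input

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a Newick string (branch lengths required on non-root edges)."""
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parser error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        length = np.zeros(len(nodes))
        tips: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                bl = nd.edge.length
                if bl is None:
                    bl = 0.0
                if bl < 0:
                    label = nd.taxon.label if nd.taxon else f"node {i}"
                    raise NewickParseError(f"negative branch length {bl} on edge above {label!r}")
                length[i] = bl
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise NewickParseError(f"unlabelled tip at node {i}")
                tips[i] = nd.taxon.label
        return cls(parent, length, tips)

    @classmethod
    def from_children(
        cls,
        children: Sequence[tuple[int, int] | None],
        heights: Sequence[float],
        labels: Sequence[str],
    ) -> "Phylogeny":
        """Build an ultrametric dendrogram from merge records.

        ``children[k]`` is None for the first ``len(labels)`` entries (leaves,
        height 0) and a pair of earlier node ids for merges; edge length above
        a node is the parent's height minus the node's height; the last record
        is the root.
        """
        n = len(children)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n)
        tips: dict[int, str] = {}
        for k, ch in enumerate(children):
            if ch is None:
                tips[k] = labels[k]
            else:
                for c in ch:
                    parent[c] = k
                    length[c] = heights[k] - heights[c]
        return cls(parent, length, tips)


def read_newick(path) -> Phylogeny:
    """Read a rooted, branch-length-bearing tree from a Newick file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise NewickParseError(f"{path}: empty file")
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path):
    """Write ``tree`` in canonical Newick form; returns ``path``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")
    return path
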