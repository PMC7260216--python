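"""Rooted binary phylogenies on a flat, postorder-indexed array layout.

Every node of a :class:`PhyloTree` carries a *postorder index* assigned at
construction: children always precede their parent and the root is the last
node.  All node-keyed tables emitted by this package (ancestral-state
marginals, character histories, ...) use these indices, and they are stable
across Newick round-trips.

Parsing and formatting of Newick itself is delegated to :mod:`dendropy`;
this module only converts between dendropy's object tree and the array
layout that the likelihood and simulation machinery operates on.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree", "TreeStructureError"]


class TreeStructureError(ValueError):
    """Raised when a tree violates the rooted-binary contract."""


@dataclass
class PhyloTree:
    """A rooted, strictly binary tree with branch lengths in Myr.

    Attributes
    ----------
    parent, left, right
        Integer arrays over postorder node indices; ``-1`` marks "absent"
        (the root's parent, a tip's children).
    blen
        Length of the edge *above* each node; the root entry is the stem
        length (0 for a crown tree).
    labels
        Tip label per node, ``None`` for internal nodes.
    """

    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    blen: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=np.float64)
        n = self.parent.size
        if not (self.left.size == self.right.size == self.blen.size == len(self.labels) == n):
            raise TreeStructureError("array lengths disagree")
        if np.any(self.blen < 0):
            raise TreeStructureError("negative branch length")
        tips = [l for l in self.labels if l is not None]
        if len(set(tips)) != len(tips):
            dup = sorted({l for l in tips if tips.count(l) > 1})
            raise TreeStructureError(f"duplicate tip labels: {dup}")
        self._tip_index = {l: i for i, l in enumerate(self.labels) if l is not None}

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.parent.size - 1

    @property
    def is_tip(self) -> np.ndarray:
        return self.left < 0

    @property
    def n_tips(self) -> int:
        return int(np.count_nonzero(self.left < 0))

    @property
    def tip_labels(self) -> list:
        """Tip labels in postorder-index order."""
        return [l for l in self.labels if l is not None]

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    @property
    def postorder(self) -> np.ndarray:
        """Node indices in postorder (the identity by construction)."""
        return np.arange(self.n_nodes)

    # ------------------------------------------------------------- traversal
    def path_to_root(self, node: int) -> list:
        """Node indices from ``node`` up to and including the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def node_depths(self) -> np.ndarray:
        """Time-depth of each node measured from the root (root = 0)."""
        depth = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):  # preorder skipping root
            depth[v] = depth[self.parent[v]] + self.blen[v]
        return depth

    def node_heights(self) -> np.ndarray:
        """Height of each node above the deepest tip (tips at 0 if ultrametric)."""
        d = self.node_depths()
        return d[self.is_tip].max() - d

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        d = self.node_depths()[self.is_tip]
        span = d.max() - d.min()
        return bool(span <= rtol * max(d.max(), 1e-300))

    def total_length(self, include_stem: bool = False) -> float:
        t = float(self.blen.sum())
        if not include_stem:
            t -= float(self.blen[self.root])
        return t

    def scale(self, c: float) -> "PhyloTree":
        """Return a copy with all branch lengths multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return PhyloTree(self.parent.copy(), self.left.copy(), self.right.copy(),
                         self.blen * c, list(self.labels))

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.left.copy(), self.right.copy(),
                         self.blen.copy(), list(self.labels))

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)
        except dendropy.utility.error.DataParseError as e:
            if "Duplicate" in str(e) or "Multiple occurrences" in str(e):
                raise TreeStructureError(f"duplicate tip labels: {e}") from e
            raise
        return cls.from_dendropy(dt)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        nodes = list(dt.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        labels: list = [None] * n
        for i, nd in enumerate(nodes):
            ch = nd.child_nodes()
            if len(ch) == 0:
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeStructureError("unlabeled tip")
                labels[i] = nd.taxon.label
            elif len(ch) == 2:
                left[i], right[i] = index[id(ch[0])], index[id(ch[1])]
                parent[index[id(ch[0])]] = i
                parent[index[id(ch[1])]] = i
            else:
                raise TreeStructureError(
                    f"tree is not strictly binary: node with {len(ch)} children")
            blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if blen[i] < 0:
                raise TreeStructureError("negative branch length in input")
        return cls(parent, left, right, blen, labels)

    def to_newick(self, precision: int = 10, annotations: dict | None = None) -> str:
        """Serialize to a Newick string.

        ``annotations`` optionally maps node index -> string; each is written
        as a ``[&...]`` comment after that node's branch length (used for
        segment-annotated character histories).
        """

        def fmt(v: int) -> str:
            if self.left[v] < 0:
                s = _quote(self.labels[v])
            else:
                s = f"({fmt(int(self.left[v]))},{fmt(int(self.right[v]))})"
            s += f":{self.blen[v]:.{precision}g}"
            if annotations and v in annotations:
                s += f"[&{annotations[v]}]"
            return s

        root = self.root
        inner = f"({fmt(int(self.left[root]))},{fmt(int(self.right[root]))})"
        if self.blen[root] > 0 or (annotations and root in annotations):
            inner += f":{self.blen[root]:.{precision}g}"
            if annotations and root in annotations:
                inner += f"[&{annotations[root]}]"
        return inner + ";"

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    # ---------------------------------------------------------------- misc
    def rotated(self, seed: int = 0) -> "PhyloTree":
        """Randomly swap children (tree is unchanged up to rotation).

        Used in tests of rotation invariance; returns a new tree whose
        postorder indexing generally differs.
        """
        rng = np.random.default_rng(seed)
        dt = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=True)
        for nd in dt.preorder_node_iter():
            ch = nd.child_nodes()
            if len(ch) == 2 and rng.random() < 0.5:
                nd.set_child_nodes([ch[1], ch[0]])
        return PhyloTree.from_dendropy(dt)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, {self.n_nodes} nodes>"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label
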