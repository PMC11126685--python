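"""Rooted phylogenetic trees: parsing, writing, traversal, ultrametricization.

The in-memory representation is a flat array-of-nodes structure tuned for the
likelihood machinery in :mod:`lichenscan.mk`: integer node ids, parent links,
per-node branch lengths and an explicit postorder.  Newick I/O goes through
dendropy; a deterministic serializer is provided so identical trees always
produce byte-identical newick strings.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "NewickParseError", "parse_newick", "write_newick"]


class NewickParseError(ValueError):
    """Raised for malformed newick input or invariant violations."""


class PhyloTree:
    """Rooted tree with branch lengths; polytomies allowed.

    Nodes are integers ``0..n_nodes-1``.  ``parent[i]`` is the parent of node
    ``i`` (``-1`` for the root), ``lengths[i]`` is the length of the branch
    above node ``i`` (0.0 for the root), ``labels[i]`` is the node label
    (mandatory and unique for tips, optional for internal nodes).
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
        root: int,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        self.root = int(root)
        n = len(self.parent)
        if not (len(self.lengths) == len(self.labels) == n):
            raise ValueError("parent/lengths/labels must have equal length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self._validate()
        self._postorder: list[int] | None = None

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        roots = [i for i, p in enumerate(self.parent) if p < 0]
        if roots != [self.root] and (len(roots) != 1 or roots[0] != self.root):
            raise ValueError(f"tree must have exactly one root, found {roots}")
        if not np.all(np.isfinite(self.lengths)):
            raise ValueError("branch lengths must be finite")
        if np.any(self.lengths < 0):
            bad = int(np.argmin(self.lengths))
            raise ValueError(f"negative branch length {self.lengths[bad]} on node {bad}")
        tips = self.tip_indices()
        seen: dict[str, int] = {}
        for i in tips:
            lab = self.labels[i]
            if lab is None or lab == "":
                raise ValueError(f"tip {i} has no label")
            if lab in seen:
                raise NewickParseError(f"duplicate tip label {lab!r}")
            seen[lab] = i

    # -- basic structure -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]

    def tip_index(self, label: str) -> int:
        for i in self.tip_indices():
            if self.labels[i] == label:
                return i
        raise KeyError(label)

    def postorder(self) -> list[int]:
        """Children-before-parents node ordering (cached)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            order.reverse()
            self._postorder = order
        return self._postorder

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.lengths[node]
        return d

    def height(self) -> float:
        return float(self.depths().max())

    def subtree_tips(self, node: int) -> list[int]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def mrca(self, tip_labels: Iterable[str]) -> int:
        """Most recent common ancestor of a set of tip labels."""
        idx = [self.tip_index(l) for l in tip_labels]
        if not idx:
            raise ValueError("mrca of empty set")
        paths = []
        for i in idx:
            path = []
            while i >= 0:
                path.append(i)
                i = self.parent[i]
            paths.append(set(path))
        common = set.intersection(*paths)
        # deepest common ancestor = the one none of whose children is common
        node = self.root
        while True:
            nxt = [c for c in self.children[node] if c in common]
            if not nxt:
                return node
            node = nxt[0]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.lengths.copy(), list(self.labels), self.root)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.depths()[self.tip_indices()]
        return float(d.max() - d.min()) <= tol

    # -- rerooting (used by gene-tree nesting) ---------------------------------------

    def reroot_above(self, node: int) -> "PhyloTree":
        """Reroot on the branch above ``node``, splitting it at its midpoint.

        Returns a new tree; the original is untouched.  Rerooting at the
        current root (or a child of the root on a zero-length branch) returns
        a copy.
        """
        if node == self.root:
            return self.copy()
        n = self.n_nodes
        parent = list(self.parent)
        lengths = list(self.lengths)
        labels = list(self.labels)
        half = lengths[node] / 2.0
        new_root = n
        parent.append(-1)
        lengths.append(0.0)
        labels.append(None)
        # path from old parent of `node` up to old root gets reversed
        path = []
        v = int(self.parent[node])
        while v >= 0:
            path.append(v)
            v = int(self.parent[v])
        old_lengths = {v: self.lengths[v] for v in path}
        parent[node] = new_root
        lengths[node] = half
        prev = new_root
        prev_len = half
        for v in path:
            upl = old_lengths[v]
            parent[v] = prev
            lengths[v] = prev_len
            prev = v
            prev_len = upl
        out = PhyloTree(parent, lengths, labels, new_root)
        return out._suppress_unifurcations()

    def _suppress_unifurcations(self) -> "PhyloTree":
        """Remove internal nodes with a single child (merging branch lengths)."""
        removable = {i for i in range(self.n_nodes) if len(self.children[i]) == 1}
        if not removable:
            return self
        root = self.root
        while len(self.children[root]) == 1:
            root = self.children[root][0]
        parent = self.parent.copy()
        lengths = self.lengths.copy()
        for i in range(self.n_nodes):
            p = int(parent[i])
            acc = lengths[i]
            while p in removable and p >= 0:
                acc += lengths[p]
                p = int(parent[p])
            parent[i] = p
            lengths[i] = acc
        keep = [i for i in range(self.n_nodes) if i not in removable]
        remap = {old: new for new, old in enumerate(keep)}
        new_parent = []
        new_lengths = []
        new_labels = []
        for old in keep:
            p = int(parent[old])
            if old == root:
                new_parent.append(-1)
                new_lengths.append(0.0)
            else:
                new_parent.append(remap[p])
                new_lengths.append(float(lengths[old]))
            new_labels.append(self.labels[old])
        return PhyloTree(new_parent, new_lengths, new_labels, remap[root])

    # -- ultrametricization ----------------------------------------------------------

    def ultrametricize(self, method: str = "extend", tol: float = 1e-9) -> "PhyloTree":
        """Make all root-to-tip path lengths equal.

        ``extend`` only lengthens terminal branches up to the maximum tip
        depth.  ``mean_path_length`` sets each internal node's age to the mean
        path length to its descendant tips (ages made monotone so branch
        lengths stay non-negative).
        """
        if method not in ("extend", "mean_path_length"):
            raise ValueError(f"unknown method {method!r}")
        out = self.copy()
        if self.is_ultrametric(tol):
            return out
        if method == "extend":
            d = out.depths()
            target = d[out.tip_indices()].max()
            for i in out.tip_indices():
                out.lengths[i] += target - d[i]
        else:
            age = np.zeros(out.n_nodes)
            for node in out.postorder():
                if out.is_tip(node):
                    age[node] = 0.0
                    continue
                acc = []
                for tip in out.subtree_tips(node):
                    # path length node -> tip
                    length = 0.0
                    v = tip
                    while v != node:
                        length += out.lengths[v]
                        v = int(out.parent[v])
                    acc.append(length)
                age[node] = float(np.mean(acc))
                kids_max = max(age[c] for c in out.children[node])
                if age[node] < kids_max:
                    age[node] = kids_max
            for node in range(out.n_nodes):
                p = int(out.parent[node])
                if p >= 0:
                    out.lengths[node] = age[p] - age[node]
        out._postorder = None
        assert out.is_ultrametric(1e-9)
        return out

    # -- newick I/O -------------------------------------------------------------------

    def to_newick(self, node_labels: dict[int, str] | None = None) -> str:
        """Deterministic newick string (10 significant digits for lengths)."""

        def fmt(x: float) -> str:
            return format(x, ".10g")

        def rec(i: int) -> str:
            if self.is_tip(i):
                core = self.labels[i]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
                lab = None
                if node_labels is not None and i in node_labels:
                    lab = node_labels[i]
                elif self.labels[i]:
                    lab = self.labels[i]
                if lab:
                    core += lab
            if i != self.root:
                core += ":" + fmt(self.lengths[i])
            return core

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, default_length: float = 1.0) -> "PhyloTree":
        return parse_newick(text, default_length=default_length)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, default_length: float = 1.0) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        missing = False
        for nd in nodes:
            if nd.parent_node is None:
                parent.append(-1)
                lengths.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                if nd.edge.length is None:
                    missing = True
                    lengths.append(default_length)
                else:
                    lengths.append(float(nd.edge.length))
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon is not None else nd.label)
            else:
                labels.append(nd.label)
        if missing:
            warnings.warn(
                f"missing branch lengths defaulted to {default_length}", stacklevel=3
            )
        return cls(parent, lengths, labels, 0)


def parse_newick(text: str, default_length: float = 1.0) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Missing branch lengths default to ``default_length`` with a warning;
    duplicate tip labels and malformed strings raise :class:`NewickParseError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        import re

        m = re.search(r"Duplicate taxon labels: (\S+)", str(exc))
        if m:
            raise NewickParseError(f"duplicate tip label {m.group(1)!r}") from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc
    try:
        return PhyloTree.from_dendropy(dtree, default_length=default_length)
    except NewickParseError:
        raise
    except ValueError as exc:
        raise NewickParseError(str(exc)) from exc


def write_newick(tree: PhyloTree, path: str | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
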