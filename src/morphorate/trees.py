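"""Array-backed rooted phylogeny container and tree I/O.

Parsing and serialization are delegated to dendropy; numerical routines
(covariance construction, Brownian simulation, pruning) work on flat
parent/branch-length arrays, with tips indexed ``0..n_tips-1`` and internal
nodes after them.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "TreeError", "read_trees", "write_newick"]


class TreeError(ValueError):
    """Raised for malformed trees or taxon mismatches."""


class PhyloTree:
    """Rooted tree with branch lengths.

    Parameters are the flat arrays produced by :meth:`from_dendropy`; use the
    classmethod constructors rather than calling ``__init__`` directly.

    Attributes
    ----------
    parent : ndarray of int
        Parent index per node (-1 for the root).
    blen : ndarray of float
        Length of the branch subtending each node (0 for the root).
    children : list of list of int
    tip_labels : list of str
        Labels of nodes ``0..n_tips-1``.
    """

    def __init__(self, parent: np.ndarray, blen: np.ndarray,
                 children: list[list[int]], tip_labels: list[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.children = children
        self.tip_labels = list(tip_labels)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeError("tip labels are not unique")
        if not np.all(np.isfinite(self.blen)) or np.any(self.blen < 0):
            raise TreeError("branch lengths must be finite and >= 0")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        # children-before-parents order; its reverse puts parents first
        order = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        self.preorder = np.array(order, dtype=int)
        self.postorder = self.preorder[::-1].copy()
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

    # ------------------------------------------------------------------ #
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"taxon {label!r} not in tree") from None

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for i in self.preorder:
            if self.parent[i] >= 0:
                d[i] = d[self.parent[i]] + self.blen[i]
        return d

    def total_length(self) -> float:
        return float(self.blen.sum())

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        td = self.depths()[: self.n_tips]
        return bool(np.ptp(td) <= tol * max(1.0, td.max()))

    def tips_under(self) -> list[list[int]]:
        """Tip indices descending from each node."""
        under: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self.postorder:
            if not self.children[i]:
                under[i] = [i]
            else:
                for c in self.children[i]:
                    under[i].extend(under[c])
        return under

    def shared_path_matrix(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """Root-to-MRCA shared path length for each pair of the given taxa.

        Diagonal entries are root-to-tip depths. This is the expected trait
        covariance per unit rate under Brownian motion.
        """
        if taxa is None:
            taxa = self.tip_labels
        idx = [self.tip_index(t) for t in taxa]
        pos = {tip: j for j, tip in enumerate(idx)}
        n = len(idx)
        depth = self.depths()
        C = np.zeros((n, n))
        under = self.tips_under()
        for node in self.postorder:
            kids = self.children[node]
            if not kids:
                continue
            groups = [[pos[t] for t in under[c] if t in pos] for c in kids]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    if groups[a] and groups[b]:
                        C[np.ix_(groups[a], groups[b])] = depth[node]
                        C[np.ix_(groups[b], groups[a])] = depth[node]
        for j, tip in enumerate(idx):
            C[j, j] = depth[tip]
        return C

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        nodes_post = list(tree.postorder_node_iter())
        tips = [nd for nd in nodes_post if nd.is_leaf()]
        index: dict[int, int] = {}
        for i, nd in enumerate(tips):
            index[id(nd)] = i
        j = len(tips)
        for nd in nodes_post:
            if not nd.is_leaf():
                index[id(nd)] = j
                j += 1
        parent = np.full(j, -1, dtype=int)
        blen = np.zeros(j)
        children: list[list[int]] = [[] for _ in range(j)]
        for nd in nodes_post:
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        labels = []
        for nd in tips:
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise TreeError("unlabeled tip in tree")
            labels.append(lab)
        return cls(parent, blen, children, labels)

    @classmethod
    def from_newick(cls, s: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=s, schema="newick",
                               preserve_underscores=True)
        return cls.from_dendropy(dt)

    def to_newick(self, precision: int = 12) -> str:
        def quote(lab: str) -> str:
            if lab and all(c.isalnum() or c in "._-" for c in lab):
                return lab
            return "'" + lab.replace("'", "''") + "'"

        def rec(i: int) -> str:
            if not self.children[i]:
                s = quote(self.tip_labels[i])
            else:
                s = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if self.parent[i] >= 0:
                s += f":{self.blen[i]:.{precision}g}"
            return s

        return rec(self.root) + ";"

    def subtree(self, taxa: Iterable[str]) -> "PhyloTree":
        """Induced subtree on the given taxa, rooted at their MRCA.

        Degree-2 nodes are suppressed with branch lengths summed; the stem
        above the new root is discarded.
        """
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self._tip_index]
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        dt = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                               preserve_underscores=True)
        dt.retain_taxa_with_labels(taxa)
        dt.suppress_unifurcations()
        # collapse a leftover unifurcate root chain onto the MRCA
        while len(dt.seed_node.child_nodes()) == 1:
            dt.seed_node = dt.seed_node.child_nodes()[0]
            dt.seed_node.parent_node = None
        return PhyloTree.from_dendropy(dt)


def _detect_schema(path: str) -> str:
    with open(path) as fh:
        head = fh.read(512).lstrip()
    return "nexus" if head.upper().startswith("#NEXUS") else "newick"


def read_trees(path: str, schema: str | None = None,
               expected_taxa: Sequence[str] | None = None) -> list[PhyloTree]:
    """Read one or more trees from a Newick or NEXUS file.

    Branch lengths are preserved as written; trees are returned in file
    order. If ``expected_taxa`` is given, each tree's tip set must equal it.
    """
    if schema is None:
        schema = _detect_schema(path)
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {schema!r}")
    tl = dendropy.TreeList.get(path=path, schema=schema,
                               preserve_underscores=True)
    if len(tl) == 0:
        raise TreeError(f"no trees found in {path}")
    out = []
    for dt in tl:
        t = PhyloTree.from_dendropy(dt)
        if expected_taxa is not None:
            tips, want = set(t.tip_labels), set(expected_taxa)
            if tips != want:
                extra = sorted(tips - want)
                lacking = sorted(want - tips)
                raise TreeError(
                    "tree/taxa mismatch: "
                    f"in tree but not in data: {extra}; "
                    f"in data but not in tree: {lacking}")
        term = t.blen[: t.n_tips]
        if np.any(term == 0):
            zero = [t.tip_labels[i] for i in np.flatnonzero(term == 0)]
            warnings.warn(f"zero-length terminal branches: {zero}")
        out.append(t)
    return out


def write_newick(trees: PhyloTree | Sequence[PhyloTree], path: str) -> None:
    if isinstance(trees, PhyloTree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")
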