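"""Rooted trees, Newick I/O, and the tree-derived matrices used by every statistic.

The tree model is a thin validating wrapper around :mod:`dendropy`. Tip order
is the first-encounter (left-to-right Newick) order and is canonical for every
matrix and permutation downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "DistanceMatrix",
    "CovMatrix",
    "TreeError",
    "NewickParseError",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "patristic_matrix",
    "vcv_matrix",
    "prune",
    "resolve_polytomies",
]


class TreeError(ValueError):
    """Raised when a tree violates the model invariants."""


class NewickParseError(ValueError):
    """Raised on malformed Newick input."""


def _format_length(value: float) -> str:
    """Canonical branch-length format: 10 significant digits, explicit decimal point."""
    s = format(float(value), ".10g")
    if "e" not in s and "E" not in s and "." not in s:
        s += ".0"
    return s


def _quote_label(label: str) -> str:
    specials = set(" \t()[]{}:;,'\"")
    if any(ch in specials for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


class Tree:
    """A rooted phylogram: one root, unique non-empty tip labels, lengths >= 0.

    Parameters
    ----------
    dtree
        A ``dendropy.Tree``. Missing edge lengths raise unless
        ``default_length`` is given (silent defaults corrupt distances).
    """

    def __init__(self, dtree: dendropy.Tree, default_length: float | None = None):
        self._dtree = dtree
        self._validate_and_fix(default_length)

    # -- construction -----------------------------------------------------
    def _validate_and_fix(self, default_length: float | None) -> None:
        dtree = self._dtree
        seen: set[str] = set()
        tips: list[str] = []
        for node in dtree.preorder_node_iter():
            is_leaf = node.is_leaf()
            if is_leaf:
                label = node.taxon.label if node.taxon is not None else node.label
                if not label:
                    raise TreeError("tip with empty label")
                if label in seen:
                    raise TreeError(f"duplicate tip label: {label!r}")
                seen.add(label)
                tips.append(label)
            if node is dtree.seed_node:
                if node.edge.length is None:
                    node.edge.length = 0.0
            elif node.edge.length is None:
                if default_length is None:
                    raise TreeError(
                        "missing branch length on edge to "
                        f"{label if is_leaf else 'an internal node'}; "
                        "pass default_length=0.0 to accept"
                    )
                node.edge.length = float(default_length)
            if node.edge.length < 0:
                raise TreeError(f"negative branch length {node.edge.length}")
        if len(tips) < 2:
            raise TreeError(f"tree must have >= 2 tips, got {len(tips)}")
        self._tip_labels: tuple[str, ...] = tuple(tips)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in first-encounter order (canonical everywhere)."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def copy(self) -> "Tree":
        return Tree(self._dtree.clone(depth=1))

    # -- basic queries -----------------------------------------------------
    def total_branch_length(self) -> float:
        return float(
            sum(
                nd.edge.length
                for nd in self._dtree.preorder_node_iter()
                if nd is not self._dtree.seed_node
            )
        )

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in tip order."""
        depth: dict[int, float] = {id(self._dtree.seed_node): 0.0}
        out: dict[str, float] = {}
        for node in self._dtree.preorder_node_iter():
            if node is not self._dtree.seed_node:
                depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
            if node.is_leaf():
                out[node.taxon.label] = depth[id(node)]
        return np.array([out[t] for t in self._tip_labels])

    def is_binary(self) -> bool:
        for node in self._dtree.preorder_internal_node_iter():
            if len(node.child_nodes()) != 2:
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_tips={self.n_tips})"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled dissimilarities: zero diagonal, label order = matrix order."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", v)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels) -> "DistanceMatrix":
        labels = tuple(labels)
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("label\t" + "\t".join(self.labels) + "\n")
        for i, lab in enumerate(self.labels):
            row = "\t".join(format(x, ".10g") for x in self.values[i])
            buf.write(f"{lab}\t{row}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        header = lines[0].split("\t")[1:]
        rows = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows.append([float(x) for x in parts[1:]])
        return cls(tuple(header), np.array(rows))


@dataclass(frozen=True)
class CovMatrix:
    """Phylogenetic variance-covariance matrix under Brownian motion.

    ``C[i, j]`` is the shared root-to-tip path length of tips i and j;
    the diagonal holds tip depths.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise ValueError("covariance matrix is not symmetric")
        object.__setattr__(self, "values", v)


# -- I/O -------------------------------------------------------------------


def read_newick(text: str, default_length: float | None = None) -> Tree:
    """Parse a single Newick tree.

    Internal node labels are read but ignored by the statistics. A missing
    branch length is an error unless ``default_length`` is supplied.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Tree(dtree, default_length=default_length)


def read_newick_file(path, default_length: float | None = None) -> Tree:
    with open(path) as fh:
        return read_newick(fh.read(), default_length=default_length)


def write_newick(tree: Tree) -> str:
    """Canonical Newick: children in stored order, 10 significant digits."""

    def render(node) -> str:
        if node.is_leaf():
            core = _quote_label(node.taxon.label)
        else:
            core = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        if node.parent_node is None:
            return core
        return core + ":" + _format_length(node.edge.length)

    return render(tree.dendropy_tree.seed_node) + ";"


def write_newick_file(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# -- matrices --------------------------------------------------------------


def patristic_matrix(tree: Tree) -> DistanceMatrix:
    """All-pairs path-length (patristic) distances among tips."""
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    labels = tree.tip_labels
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)


def vcv_matrix(tree: Tree) -> CovMatrix:
    """Brownian-motion covariance: C[i,j] = depth of the MRCA of tips i, j."""
    labels = tree.tip_labels
    pos = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    dtree = tree.dendropy_tree
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    tipsets: dict[int, list[int]] = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            k = pos[node.taxon.label]
            tipsets[id(node)] = [k]
            C[k, k] = depth[id(node)]
        else:
            groups = [tipsets.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.array(groups[a])
                    ib = np.array(groups[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            tipsets[id(node)] = [k for g in groups for k in g]
    return CovMatrix(labels, C)


def prune(tree: Tree, keep) -> Tree:
    """Induced subtree on ``keep``; unifurcations collapsed with lengths summed.

    Patristic distances among kept tips are unchanged.
    """
    keep = set(keep)
    unknown = sorted(keep - set(tree.tip_labels))
    if unknown:
        raise TreeError(f"labels not in tree: {unknown}")
    if len(keep) < 2:
        raise TreeError(f"need >= 2 tips to prune to, got {len(keep)}")
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    sub.seed_node.edge.length = 0.0
    # a root with a single child can survive extraction; collapse it
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        child.edge.length = 0.0
        sub.seed_node = child
        child.parent_node = None
    return Tree(sub)


def resolve_polytomies(tree: Tree, epsilon: float = 0.0) -> Tree:
    """Arbitrarily (deterministically) resolve multifurcations into bifurcations.

    A degree-k polytomy receives k-2 new internal nodes, each on a branch of
    length ``epsilon``; pairwise tip distances change by at most (k-2)*epsilon.
    Already-binary trees are returned as an unmodified copy.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    out = tree.copy()
    dtree = out.dendropy_tree
    for node in list(dtree.postorder_internal_node_iter()):
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            a, b = children[0], children[1]
            joint = dendropy.Node()
            joint.edge.length = float(epsilon)
            node.remove_child(a)
            node.remove_child(b)
            joint.add_child(a)
            joint.add_child(b)
            node.insert_child(0, joint)
    return Tree(dtree)
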