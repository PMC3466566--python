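"""Penalized-likelihood rate smoothing: phylogram -> ultrametric chronogram.

Trait-based statistics assume branch lengths proportional to time. A phylogram
measured in substitutions/site is converted by jointly estimating node ages and
per-branch substitution rates, maximizing a Poisson-type log-likelihood for the
observed branch lengths while penalizing rate changes between adjacent branches:

    minimize  -sum_j [ b_j * log(r_j * t_j) - r_j * t_j ]
              + lambda * sum_{j: parent edge exists} (r_j - r_parent(j))^2

where b_j is the input branch length, t_j the estimated branch duration and
r_j the estimated rate. The root age is fixed (default 1.0: relative
evolutionary units), tips are at age 0. Larger lambda pulls the solution
toward a global molecular clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .treeio import Tree

__all__ = ["SmoothingConfig", "Chronogram", "rate_smooth", "is_ultrametric"]

_FRACTION_BOUND = 1e-4
_LOG_RATE_BOUND = 25.0


@dataclass(frozen=True)
class SmoothingConfig:
    """Parameters of the penalized-likelihood smoother.

    lambda_ is the roughness weight (0 = pure likelihood; large = clock-like);
    the default mirrors common practice for protein phylograms.
    """

    lambda_: float = 0.8
    max_iterations: int = 1000
    tolerance: float = 1e-10
    root_age: float = 1.0

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.root_age <= 0:
            raise ValueError("root_age must be > 0")


@dataclass(frozen=True)
class Chronogram:
    """An ultrametric tree with node ages and per-branch rates.

    ``tree`` carries branch *durations*; ``ages``/``rates`` are keyed by tip
    label for leaves and ``nodeK`` (preorder index K) for internal nodes. The
    root has no rate. ``objective`` is the penalized objective at the returned
    solution (NaN when the chronogram was not produced by the smoother).
    """

    tree: Tree
    ages: dict = field(repr=False)
    rates: dict = field(repr=False)
    objective: float = float("nan")

    @property
    def root_age(self) -> float:
        return float(max(self.ages.values()))

    def age_table(self) -> pd.DataFrame:
        rows = [
            {"node": k, "age": self.ages[k], "rate": self.rates.get(k, np.nan)}
            for k in self.ages
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_ultrametric_tree(cls, tree: Tree, tol: float = 1e-8) -> "Chronogram":
        """Wrap an already-ultrametric tree; all rates set to 1."""
        if not is_ultrametric(tree, tol=tol):
            raise ValueError("tree is not ultrametric within tolerance")
        keys, _, _, parents, lengths, _ = _index_tree(tree)
        depth = np.zeros(len(keys))
        for i in range(1, len(keys)):
            depth[i] = depth[parents[i]] + lengths[i]
        root_age = max(
            depth[i] for i, k in enumerate(keys) if not isinstance(k, tuple)
        )
        ages, rates = {}, {}
        for i, key in enumerate(keys):
            name = key if isinstance(key, str) else key[0]
            ages[name] = max(root_age - depth[i], 0.0)
            if i > 0:
                rates[name] = 1.0
        # exact tip ages
        for lab in tree.tip_labels:
            ages[lab] = 0.0
        return cls(tree=tree.copy(), ages=ages, rates=rates)


def is_ultrametric(tree: Tree, tol: float = 1e-8) -> bool:
    """True iff the spread of root-to-tip depths is at most ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    depths = tree.tip_depths()
    return float(depths.max() - depths.min()) <= tol


def _index_tree(tree: Tree):
    """Preorder node indexing.

    Returns (keys, nodes, is_tip, parent_index, branch_lengths, children_of).
    keys[i] is the tip label for leaves and ("nodeK",) for internal nodes.
    """
    dtree = tree.dendropy_tree
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n_internal = 0
    keys = []
    is_tip = np.zeros(len(nodes), dtype=bool)
    parents = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    children: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            keys.append(nd.taxon.label)
            is_tip[i] = True
        else:
            keys.append((f"node{n_internal}",))
            n_internal += 1
        if nd.parent_node is not None:
            parents[i] = index[id(nd.parent_node)]
            children[parents[i]].append(i)
            lengths[i] = nd.edge.length
    return keys, nodes, is_tip, parents, lengths, children


def _objective(b, t, r, lam, penalty_pairs, root_edges):
    """Penalized objective; 0*log(.) terms contribute 0.

    The roughness term sums squared rate differences over parent-child edge
    pairs plus the variance of the rates on the root's child edges (without
    the root term the two root subtrees decouple: each could rescale its
    rates against its subtree-root age along a flat ridge).
    """
    t = np.maximum(t, 1e-300)
    pos = b > 0
    loglik = -(b[pos] * np.log(r[pos] * t[pos])).sum() + (r * t).sum()
    child, parent = penalty_pairs
    rough = ((r[child] - r[parent]) ** 2).sum() if len(child) else 0.0
    rough += r[root_edges].var()
    return loglik + lam * rough


def rate_smooth(tree: Tree, config: SmoothingConfig = SmoothingConfig()) -> Chronogram:
    """Fit node ages and branch rates by penalized likelihood.

    Requires a binary tree (resolve polytomies first) with at least one
    positive branch length. Deterministic: initialization takes ages from
    node heights rescaled to the root age and rates from b_j / t_j.
    """
    if not tree.is_binary():
        raise ValueError(
            "rate_smooth requires a binary tree; apply resolve_polytomies first"
        )
    if tree.n_tips < 3:
        raise ValueError("rate_smooth requires >= 3 tips")
    keys, nodes, is_tip, parents, lengths, children = _index_tree(tree)
    if not (lengths > 0).any():
        raise ValueError("all branch lengths are zero; nothing to smooth")

    n_nodes = len(nodes)
    internal = np.flatnonzero(~is_tip)  # preorder; internal[0] is the root
    free_internal = internal[1:]  # root age is fixed
    edge_nodes = np.arange(1, n_nodes)  # node i owns the edge to its parent
    b = lengths[1:]

    # roughness pairs: edge of node i vs edge of its (non-root) parent
    child_e, parent_e = [], []
    for i in range(1, n_nodes):
        p = parents[i]
        if p != 0:
            child_e.append(i - 1)
            parent_e.append(p - 1)
    penalty_pairs = (np.array(child_e, dtype=int), np.array(parent_e, dtype=int))
    root_edges = np.array(
        [i - 1 for i in range(1, n_nodes) if parents[i] == 0], dtype=int
    )

    # node heights (max distance to a descendant tip) for initial ages
    height = np.zeros(n_nodes)
    for i in range(n_nodes - 1, -1, -1):
        if not is_tip[i]:
            height[i] = max(height[c] + lengths[c] for c in children[i])
    if height[0] <= 0:
        raise ValueError("tree height is zero")

    ages0 = np.zeros(n_nodes)
    ages0[~is_tip] = config.root_age * height[~is_tip] / height[0]
    ages0[0] = config.root_age

    def ages_from_fractions(frac):
        ages = np.zeros(n_nodes)
        ages[0] = config.root_age
        for k, i in enumerate(free_internal):
            ages[i] = frac[k] * ages[parents[i]]
        return ages

    frac0 = np.empty(len(free_internal))
    for k, i in enumerate(free_internal):
        pa = ages0[parents[i]]
        frac0[k] = np.clip(
            ages0[i] / pa if pa > 0 else 0.5,
            _FRACTION_BOUND,
            1 - _FRACTION_BOUND,
        )
    ages0 = ages_from_fractions(frac0)
    t0 = np.maximum(ages0[parents[1:]] - ages0[1:], 1e-8)
    r0 = np.clip(b / t0, 1e-6, 1e6)

    n_f = len(frac0)

    def unpack(x):
        frac = x[:n_f]
        r = np.exp(x[n_f:])
        ages = ages_from_fractions(frac)
        t = ages[parents[1:]] - ages[1:]
        return ages, t, r

    child_e, parent_e = penalty_pairs
    # postorder (reverse preorder) for subtree accumulations
    postorder = range(n_nodes - 1, 0, -1)

    def fun_and_grad(x):
        ages, t, r = unpack(x)
        t = np.maximum(t, 1e-12)
        value = _objective(b, t, r, config.lambda_, penalty_pairs, root_edges)

        # d(phi)/dr and d(phi)/dt, edge-indexed (edge j = node j+1)
        dr = t - np.where(r > 0, b / r, 0.0)
        if len(child_e):
            diff = r[child_e] - r[parent_e]
            np.add.at(dr, child_e, 2 * config.lambda_ * diff)
            np.add.at(dr, parent_e, -2 * config.lambda_ * diff)
        m_root = len(root_edges)
        dr[root_edges] += (
            config.lambda_ * (2.0 / m_root) * (r[root_edges] - r[root_edges].mean())
        )
        grad_logr = dr * r
        dt = r - b / t

        # d(phi)/d(age_i) = -dt(edge of i) + sum over children c of dt(edge c)
        g_age = np.zeros(n_nodes)
        g_age[1:] -= dt
        np.add.at(g_age, parents[1:], dt)
        # chain to fractions: a_i = root_age * prod of f along root->i, so
        # d(phi)/d(f_k) = (1/f_k) * sum_{i in subtree(k)} g_age_i * a_i
        s = g_age * ages
        s[is_tip] = 0.0  # tip ages are fixed at 0
        acc = s.copy()
        for i in postorder:
            acc[parents[i]] += acc[i]
        frac = x[:n_f]
        grad_f = acc[free_internal] / frac
        return value, np.concatenate([grad_f, grad_logr])

    x0 = np.concatenate([frac0, np.log(r0)])
    bounds = [(_FRACTION_BOUND, 1 - _FRACTION_BOUND)] * n_f + [
        (-_LOG_RATE_BOUND, _LOG_RATE_BOUND)
    ] * len(edge_nodes)
    f0 = fun_and_grad(x0)[0]
    res = minimize(
        fun_and_grad,
        x0,
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={
            "maxiter": config.max_iterations,
            "maxfun": 50 * config.max_iterations,
            "ftol": config.tolerance,
            "gtol": 1e-12,
        },
    )
    x = res.x if res.fun <= f0 else x0
    ages, t, r = unpack(x)

    out = tree.copy()
    out_nodes = list(out.dendropy_tree.preorder_node_iter())
    for i, nd in enumerate(out_nodes):
        if i > 0:
            nd.edge.length = float(max(t[i - 1], 0.0))
    smoothed = Tree(out.dendropy_tree)

    age_map, rate_map = {}, {}
    for i, key in enumerate(keys):
        name = key if isinstance(key, str) else key[0]
        age_map[name] = float(ages[i])
        if i > 0:
            rate_map[name] = float(r[i - 1])
    return Chronogram(
        tree=smoothed, ages=age_map, rates=rate_map, objective=float(min(res.fun, f0))
    )
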