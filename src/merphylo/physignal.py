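"""Blomberg's K and its permutation test for gene presence/absence traits.

K compares the observed signal of a trait to the signal expected if the trait
had evolved by Brownian motion along the tree:

    K = (MSE0 / MSE) / E_BM[MSE0 / MSE]

with MSE0 the variance of tip values about the GLS phylogenetic mean, MSE the
GLS mean-squared error under the Brownian covariance C, and
E_BM[MSE0/MSE] = [tr(C) - n / (1'C^-1 1)] / (n - 1). K ~ 1 under Brownian
motion, K >> 1 for strongly conserved (clumped) traits, K -> 0 for random or
convergent patterns. Presence/absence traits are scored as numeric 0/1.

Significance is assessed by shuffling taxa labels across the tips: the test
statistic is the variance of phylogenetically independent contrasts (PIC), and
a trait is significant when its observed contrast variance is LOW relative to
the permutation null (strong signal = similar values in adjacent tips = small
contrasts).

Two independent routes compute K: a dense C-matrix route and a Felsenstein
pruning (contrasts) route; they agree to numerical precision on binary trees
and cross-validate each other in the test suite.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import TraitMatrix, round_half_up, subset_by_replicon
from .treeio import CovMatrix, Tree, prune, resolve_polytomies, vcv_matrix

__all__ = [
    "SignalResult",
    "phylo_mean",
    "blomberg_k",
    "pic",
    "signal_test",
    "multi_signal",
    "plasmid_differential",
    "trait_rng",
]

_RIDGE_SCALE = 1e-12


@dataclass(frozen=True)
class SignalResult:
    """One trait's phylogenetic signal on one tree (a signal-table row)."""

    trait: str
    k: float
    p: float
    n_permutations: int
    pic_variance_obs: float
    null_quantiles: dict
    n_tips: int

    def __post_init__(self):
        if self.n_permutations > 0 and not (
            self.p >= 1.0 / (self.n_permutations + 1) - 1e-12
        ):
            raise ValueError("permutation p below its attainable minimum")


def _solve_regularized(C: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve C y = rhs, adding a small ridge if C is numerically singular."""
    try:
        cond = np.linalg.cond(C)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        C = C + np.eye(len(C)) * (_RIDGE_SCALE * np.trace(C) / len(C))
    try:
        return np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance matrix is singular") from exc


def phylo_mean(x, C: CovMatrix) -> float:
    """GLS phylogenetic mean a = (1'C^-1 x) / (1'C^-1 1)."""
    x = np.asarray(x, dtype=float)
    V = C.values
    if len(x) != len(V):
        raise ValueError("trait vector length does not match covariance matrix")
    ones = np.ones(len(x))
    sol = _solve_regularized(V, np.column_stack([x, ones]))
    return float(ones @ sol[:, 0] / (ones @ sol[:, 1]))


def _k_from_vcv(tree: Tree, x: np.ndarray) -> float:
    C = vcv_matrix(tree).values
    n = len(x)
    ones = np.ones(n)
    sol = _solve_regularized(C, np.column_stack([x, ones]))
    Cinv_x, Cinv_1 = sol[:, 0], sol[:, 1]
    denom_1 = ones @ Cinv_1
    a = float(ones @ Cinv_x / denom_1)
    resid = x - a
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ _solve_regularized(C, resid)) / (n - 1)
    expected = (np.trace(C) - n / denom_1) / (n - 1)
    return (mse0 / mse) / expected


def pic_machinery(tree: Tree, epsilon: float = 1e-8):
    """Linear-operator form of Felsenstein pruning.

    Returns (L, w, v_root) with contrasts = L @ x (shape (n-1, n)), the root
    state estimate a = w @ x (the GLS mean), and v_root = 1 / (1'C^-1 1).
    Zero-length branches are extended by ``epsilon`` so contrasts stay finite.
    """
    if not tree.is_binary():
        raise ValueError("contrasts require a binary tree; resolve polytomies first")
    labels = tree.tip_labels
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    contrasts = []
    store: dict[int, tuple[np.ndarray, float]] = {}
    dtree = tree.dendropy_tree
    for node in dtree.postorder_node_iter():
        blen = 0.0 if node.parent_node is None else float(node.edge.length)
        if blen <= 0 and node.parent_node is not None:
            blen = epsilon
        if node.is_leaf():
            coeff = np.zeros(n)
            coeff[pos[node.taxon.label]] = 1.0
            store[id(node)] = (coeff, blen)
        else:
            (cL, vL), (cR, vR) = (store.pop(id(c)) for c in node.child_nodes())
            denom = vL + vR
            if denom <= 0:
                denom = 2 * epsilon if epsilon > 0 else 1e-300
            contrasts.append((cL - cR) / np.sqrt(denom))
            coeff = (vR * cL + vL * cR) / denom
            store[id(node)] = (coeff, blen + vL * vR / denom)
    w, v_root = store[id(dtree.seed_node)]
    return np.array(contrasts), w, v_root


def pic(tree: Tree, x) -> np.ndarray:
    """Standardized phylogenetically independent contrasts (n-1 of them)."""
    x = np.asarray(x, dtype=float)
    L, _, _ = pic_machinery(tree)
    return L @ x


def _k_from_pic(tree: Tree, x: np.ndarray) -> float:
    L, w, v_root = pic_machinery(tree)
    n = len(x)
    a = float(w @ x)
    resid = x - a
    mse0 = float(resid @ resid) / (n - 1)
    contrasts = L @ x
    mse = float(contrasts @ contrasts) / (n - 1)
    trace_C = float(tree.tip_depths().sum())
    expected = (trace_C - n * v_root) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: Tree, x, method: str = "vcv") -> float:
    """Blomberg's K for a tip-value vector ordered as ``tree.tip_labels``.

    ``method`` selects the dense C-matrix route ("vcv") or the contrasts
    route ("pic"); the two agree to numerical precision and are cross-checked
    against each other in the test suite.
    """
    x = np.asarray(x, dtype=float)
    if tree.n_tips < 4:
        raise ValueError("Blomberg's K requires at least 4 tips")
    if len(x) != tree.n_tips:
        raise ValueError("trait vector length does not match tip count")
    if np.ptp(x) == 0:
        raise ValueError("trait has no variation")
    if method == "vcv":
        return _k_from_vcv(tree, x)
    if method == "pic":
        t = tree if tree.is_binary() else resolve_polytomies(tree, epsilon=0.0)
        return _k_from_pic(t, x)
    raise ValueError(f"unknown method {method!r}")


def signal_test(
    tree: Tree,
    x,
    n_perm: int = 999,
    seed=0,
    trait: str = "trait",
) -> SignalResult:
    """K plus a tip-shuffling permutation test on the PIC variance.

    p = (1 + #{permutations with contrast variance <= observed}) / (1 + n_perm),
    ties counted as extreme; p never reaches 0.
    """
    x = np.asarray(x, dtype=float)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    k = blomberg_k(tree, x, method="vcv")
    t = tree if tree.is_binary() else resolve_polytomies(tree, epsilon=1e-8)
    L, _, _ = pic_machinery(t)
    n = len(x)
    obs_var = float(((L @ x) ** 2).sum()) / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = x[rng.permutation(n)]
    null_vars = ((L @ perms.T) ** 2).sum(axis=0) / (n - 1)
    tol = 1e-12 * max(1.0, obs_var)
    count = int((null_vars <= obs_var + tol).sum())
    p = (1 + count) / (1 + n_perm)
    q = np.quantile(null_vars, [0.025, 0.5, 0.975])
    return SignalResult(
        trait=trait,
        k=k,
        p=p,
        n_permutations=n_perm,
        pic_variance_obs=obs_var,
        null_quantiles={"q025": float(q[0]), "q500": float(q[1]), "q975": float(q[2])},
        n_tips=n,
    )


def trait_rng(master_seed: int, trait: str) -> np.random.Generator:
    """Per-trait random stream: order-independent, derived from the trait name."""
    return np.random.default_rng([int(master_seed), zlib.crc32(trait.encode())])


def _trait_seed(master_seed: int, trait: str):
    return [int(master_seed), zlib.crc32(trait.encode())]


def multi_signal(
    tree: Tree,
    matrix: TraitMatrix,
    n_perm: int = 999,
    seed: int = 0,
    traits=None,
) -> pd.DataFrame:
    """Signal table: one row per registered trait (the Table-1-style output).

    The tree is pruned to the taxa shared with the catalog. Traits without
    variation among the used tips get an NA row (K = p = NaN) but still report
    their genomic distribution. Per-trait random streams are derived from the
    master seed and the trait name, so results do not depend on column order.
    """
    taxa = set(matrix.taxa)
    common = [t for t in tree.tip_labels if t in taxa]
    if not common:
        raise ValueError("no taxa shared between tree and catalog")
    t = tree if len(common) == tree.n_tips else prune(tree, common)
    if traits is None:
        traits = [c for c in matrix.trait_names]
    rows = []
    n = len(common)
    for trait in traits:
        x = matrix.trait_vector(trait, taxa=t.tip_labels)
        presence = int(x.sum())
        absence = n - presence
        percent = round_half_up(100.0 * presence / n, 1)
        if np.ptp(x) == 0:
            rows.append(
                {
                    "trait": trait,
                    "K": np.nan,
                    "p": np.nan,
                    "presence": presence,
                    "absence": absence,
                    "percent": percent,
                    "n_tips": n,
                }
            )
            continue
        res = signal_test(t, x, n_perm=n_perm, seed=_trait_seed(seed, trait), trait=trait)
        rows.append(
            {
                "trait": trait,
                "K": res.k,
                "p": res.p,
                "presence": presence,
                "absence": absence,
                "percent": percent,
                "n_tips": n,
            }
        )
    return pd.DataFrame(rows)


def plasmid_differential(
    tree_all: Tree,
    tree_chrom: Tree,
    matrix: TraitMatrix,
    n_perm: int = 999,
    seed: int = 0,
    traits=None,
) -> pd.DataFrame:
    """Paired K with/without plasmid-borne operons; delta = K_without - K_with.

    A positive delta means plasmid operons depress the signal for vertical
    inheritance of that gene, the pattern expected under plasmid-borne lateral
    transfer. Both arms use the same per-trait seed policy. Sorted by delta,
    largest first.
    """
    arm_all = multi_signal(tree_all, matrix, n_perm=n_perm, seed=seed, traits=traits)
    chrom = subset_by_replicon(matrix, "chromosome")
    arm_chrom = multi_signal(tree_chrom, chrom, n_perm=n_perm, seed=seed, traits=traits)
    merged = arm_all.merge(
        arm_chrom, on="trait", suffixes=("_with", "_without")
    )
    merged["delta_k"] = merged["K_without"] - merged["K_with"]
    out = merged[
        [
            "trait",
            "K_with",
            "p_with",
            "K_without",
            "p_without",
            "delta_k",
        ]
    ].sort_values("delta_k", ascending=False, na_position="last")
    return out.reset_index(drop=True)
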