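"""Distance-matrix and co-occurrence statistics.

Rao's quadratic-entropy dissimilarity between (weighted) groups of tips,
Mantel permutation correlation between two labeled distance matrices (the
gene-tree vs species-tree congruence test), pairwise Pearson/phi co-occurrence
of binary gene traits with permutation p-values, and the plasmid-bias
regression of per-gene percentages with and without plasmid-borne operons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitMatrix, round_half_up, subset_by_replicon, trait_counts
from .treeio import DistanceMatrix, Tree, patristic_matrix

__all__ = [
    "MantelResult",
    "CooccurrenceResult",
    "rao_dissimilarity",
    "mantel",
    "mantel_subset",
    "cooccurrence_matrix",
    "plasmid_bias_regression",
    "bias_regression_from_pairs",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    n_labels: int


@dataclass(frozen=True)
class CooccurrenceResult:
    """Pairwise trait co-occurrence: Pearson R (= phi for 0/1) and p-values."""

    traits: tuple[str, ...]
    r: pd.DataFrame = field(repr=False)
    p: pd.DataFrame = field(repr=False)


def rao_dissimilarity(tree: Tree, groups: dict) -> DistanceMatrix:
    """Rao dissimilarity D[i,j] = sum_kl p_ik p_jl d(k,l) over patristic d.

    ``groups`` maps group name -> {tip label: weight}; weights within a group
    must sum to 1. Singleton groups reduce exactly to patristic distance with
    zero self-dissimilarity. The diagonal (intra-group quadratic entropy) is
    forced to zero in the returned matrix so it remains a valid dissimilarity;
    use the returned ``intra`` attribute pattern via `rao_quadratic_entropy`
    when the within-group term is needed.
    """
    if not groups:
        raise ValueError("no groups given")
    d = patristic_matrix(tree)
    pos = {lab: i for i, lab in enumerate(d.labels)}
    names = tuple(groups)
    P = np.zeros((len(names), len(d.labels)))
    for gi, name in enumerate(names):
        members = groups[name]
        if not members:
            raise ValueError(f"group {name!r} is empty")
        unknown = sorted(set(members) - set(d.labels))
        if unknown:
            raise ValueError(f"group {name!r} has labels not in tree: {unknown}")
        w = np.array(list(members.values()), dtype=float)
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"group {name!r} weights sum to {w.sum()}, not 1")
        for lab, wt in members.items():
            P[gi, pos[lab]] += wt
    D = P @ d.values @ P.T
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(names, D)


def rao_quadratic_entropy(tree: Tree, members: dict) -> float:
    """Within-group Rao quadratic entropy sum_kl p_k p_l d(k,l)."""
    d = patristic_matrix(tree)
    pos = {lab: i for i, lab in enumerate(d.labels)}
    idx = [pos[lab] for lab in members]
    w = np.array(list(members.values()), dtype=float)
    return float(w @ d.values[np.ix_(idx, idx)] @ w)


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(values), k=1)
    return values[iu]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed=0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two labeled distance matrices.

    r is the Pearson correlation over off-diagonal (upper-triangle) pairs;
    d2 is reordered to d1's labels first. The null permutes rows/columns of
    d2 jointly; p uses the add-one rule. One-sided "greater" by default (the
    directional claim of positive gene-tree/species-tree congruence);
    "two-sided" available.
    """
    if set(d1.labels) != set(d2.labels):
        only1 = sorted(set(d1.labels) - set(d2.labels))
        only2 = sorted(set(d2.labels) - set(d1.labels))
        raise ValueError(f"label mismatch: only in d1 {only1}, only in d2 {only2}")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("Mantel test requires >= 4 labels")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    d2 = d2.submatrix(d1.labels)
    a = _upper(d1.values)
    B = d2.values
    r_obs = float(stats.pearsonr(a, _upper(B)).statistic)
    rng = np.random.default_rng(seed)
    a_c = a - a.mean()
    a_norm = np.sqrt((a_c**2).sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b = _upper(B[np.ix_(perm, perm)])
        b_c = b - b.mean()
        denom = a_norm * np.sqrt((b_c**2).sum())
        r_p = float(a_c @ b_c / denom) if denom > 0 else 0.0
        if alternative == "greater":
            extreme = r_p >= r_obs - 1e-12
        elif alternative == "two-sided":
            extreme = abs(r_p) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        count += extreme
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_permutations=n_perm, n_labels=n)


def mantel_subset(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed=0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test on the submatrices induced by ``labels`` (e.g. one domain)."""
    labels = tuple(labels)
    if len(labels) < 4:
        raise ValueError("subset must have >= 4 labels")
    return mantel(
        d1.submatrix(labels),
        d2.submatrix(labels),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


def cooccurrence_matrix(
    matrix: TraitMatrix,
    n_perm: int = 999,
    seed: int = 0,
    traits=None,
) -> CooccurrenceResult:
    """Pairwise co-occurrence of binary traits across operons.

    Pearson R on 0/1 columns (identical to the phi coefficient of the 2x2
    table); p-values by column permutation, two-sided, add-one rule. Traits
    with no variation get NaN rows/columns. The observations are operons.
    """
    if traits is None:
        traits = list(matrix.trait_names)
    X = np.column_stack([matrix.trait_vector(t) for t in traits])
    varying = [i for i in range(len(traits)) if np.ptp(X[:, i]) > 0]
    if len(varying) < 2:
        raise ValueError("need at least 2 traits with variation")
    m = len(traits)
    R = np.full((m, m), np.nan)
    P = np.full((m, m), np.nan)
    for i in varying:
        R[i, i] = 1.0
        P[i, i] = 0.0
    rng = np.random.default_rng(seed)
    nrows = X.shape[0]
    for ai in range(len(varying)):
        i = varying[ai]
        xi = X[:, i]
        xi_c = xi - xi.mean()
        xi_norm = np.sqrt((xi_c**2).sum())
        others = varying[ai + 1 :]
        if not others:
            continue
        Y = X[:, others]
        Y_c = Y - Y.mean(axis=0)
        Y_norm = np.sqrt((Y_c**2).sum(axis=0))
        r_obs = (xi_c @ Y_c) / (xi_norm * Y_norm)
        perms = np.empty((n_perm, nrows))
        for k in range(n_perm):
            perms[k] = xi_c[rng.permutation(nrows)]
        r_null = (perms @ Y_c) / (xi_norm * Y_norm)  # (n_perm, len(others))
        extreme = (np.abs(r_null) >= np.abs(r_obs)[None, :] - 1e-12).sum(axis=0)
        p = (1 + extreme) / (1 + n_perm)
        for k, j in enumerate(others):
            R[i, j] = R[j, i] = r_obs[k]
            P[i, j] = P[j, i] = p[k]
    rdf = pd.DataFrame(R, index=traits, columns=traits)
    pdf = pd.DataFrame(P, index=traits, columns=traits)
    return CooccurrenceResult(traits=tuple(traits), r=rdf, p=pdf)


def bias_regression_from_pairs(pairs: pd.DataFrame):
    """OLS of percent-with-plasmids (y) on percent-chromosome-only (x).

    ``pairs`` needs columns trait, percent_chromosome, percent_all. Returns
    (slope, intercept, pairs-with-flag) where ``plasmid_enriched`` marks genes
    above the 1:1 line (more common once plasmid operons are included).
    """
    x = pairs["percent_chromosome"].to_numpy(dtype=float)
    y = pairs["percent_all"].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 traits to regress")
    fit = stats.linregress(x, y)
    out = pairs.copy()
    out["plasmid_enriched"] = out["percent_all"] > out["percent_chromosome"]
    return float(fit.slope), float(fit.intercept), out


def plasmid_bias_regression(matrix: TraitMatrix, traits=None):
    """Regress per-gene percentages with vs without plasmid-borne operons.

    For each registered trait, x = percent among chromosome-only operons and
    y = percent among all operons, each rounded half-up to one decimal before
    fitting (so a printed summary table reproduces the fit inputs exactly).
    Slope 1 / intercept 0 means no replicon bias; genes above the 1:1 line are
    plasmid-enriched. Errors when the chromosomal class is empty (the x-axis
    would be undefined); an empty plasmid class degenerates to the 1:1 line.
    """
    chrom = subset_by_replicon(matrix, "chromosome")
    if chrom.n_operons == 0:
        raise ValueError("no chromosomal operons: percentages undefined")
    if traits is None:
        traits = list(matrix.trait_names)
    rows = []
    for trait in traits:
        _, _, pct_all = trait_counts(matrix, trait)
        _, _, pct_chrom = trait_counts(chrom, trait)
        rows.append(
            {
                "trait": trait,
                "percent_chromosome": round_half_up(pct_chrom, 1),
                "percent_all": round_half_up(pct_all, 1),
            }
        )
    return bias_regression_from_pairs(pd.DataFrame(rows))
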