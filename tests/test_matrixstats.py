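"""Rao dissimilarity, Mantel, co-occurrence and the plasmid-bias regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from merphylo import (
    DistanceMatrix,
    TraitMatrix,
    cooccurrence_matrix,
    mantel,
    mantel_subset,
    patristic_matrix,
    plasmid_bias_regression,
    rao_dissimilarity,
    read_newick,
)
from merphylo.matrixstats import bias_regression_from_pairs, rao_quadratic_entropy


def binary_catalog(columns: dict, replicon=None):
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(
        {
            "operon_id": [f"op{i}" for i in range(n)],
            "taxon_label": [f"t{i}" for i in range(n)],
            "genome_id": [f"g{i}" for i in range(n)],
            "replicon": replicon or ["chromosome"] * n,
            "merA": [1] * n,
            **columns,
        }
    )
    return TraitMatrix(df)


class TestRao:
    def test_singletons_reduce_to_patristic(self, balanced4):
        groups = {lab: {lab: 1.0} for lab in balanced4.tip_labels}
        D = rao_dissimilarity(balanced4, groups)
        np.testing.assert_allclose(D.values, patristic_matrix(balanced4).values)

    def test_hand_summation_within_group(self):
        t = read_newick("(A:1,B:1);")
        # sum p_k p_l d(k,l) = 2 * (0.5*0.5*2) = 1.0
        assert rao_quadratic_entropy(t, {"A": 0.5, "B": 0.5}) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, random_chronogram):
        tree = random_chronogram(n_tips=5, seed=3).tree
        labs = tree.tip_labels
        groups = {
            "g1": {labs[0]: 0.5, labs[1]: 0.5},
            "g2": {labs[2]: 0.25, labs[3]: 0.75},
            "g3": {labs[4]: 1.0},
        }
        D = rao_dissimilarity(tree, groups)
        d = patristic_matrix(tree)
        for ga, gb in itertools.combinations(groups, 2):
            expected = sum(
                wa * wb * d.get(a, b)
                for a, wa in groups[ga].items()
                for b, wb in groups[gb].items()
            )
            assert D.get(ga, gb) == pytest.approx(expected)

    def test_unknown_member_rejected(self, balanced4):
        with pytest.raises(ValueError, match="not in tree"):
            rao_dissimilarity(balanced4, {"g": {"Z": 1.0}})

    def test_weights_must_sum_to_one(self, balanced4):
        with pytest.raises(ValueError, match="sum"):
            rao_dissimilarity(balanced4, {"g": {"A": 0.3, "B": 0.3}})

    def test_singleton_metric_triangle_inequality(self, random_chronogram):
        tree = random_chronogram(n_tips=7, seed=6).tree
        D = rao_dissimilarity(tree, {l: {l: 1.0} for l in tree.tip_labels})
        v = D.values
        for i, j, k in itertools.permutations(range(7), 3):
            assert v[i, j] <= v[i, k] + v[k, j] + 1e-9


def random_distance(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    v = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return DistanceMatrix(tuple(labels or (f"l{i}" for i in range(n))), v)


class TestMantel:
    def test_self_comparison(self):
        D = random_distance(8, 0)
        res = mantel(D, D, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_affine_invariance(self):
        D = random_distance(7, 2)
        off = ~np.eye(7, dtype=bool)
        v2 = 2 * D.values + 3 * off
        res = mantel(D, DistanceMatrix(D.labels, v2), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_symmetry_in_arguments(self):
        d1, d2 = random_distance(6, 3), random_distance(6, 4)
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(
            mantel(d2, d1, n_perm=99, seed=0).r
        )

    def test_label_reordering_handled(self):
        d1 = random_distance(6, 5)
        perm = [3, 1, 0, 5, 4, 2]
        d2 = DistanceMatrix(
            tuple(d1.labels[i] for i in perm), d1.values[np.ix_(perm, perm)]
        )
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_exhaustive_enumeration_oracle(self):
        """MC p at n_perm=10000 matches full enumeration over all 24 relabelings."""
        d1, d2 = random_distance(4, 7), random_distance(4, 8)
        a = d1.values[np.triu_indices(4, 1)]
        r_obs = stats.pearsonr(a, d2.values[np.triu_indices(4, 1)]).statistic
        hits = 0
        perms = list(itertools.permutations(range(4)))
        for p in perms:
            b = d2.values[np.ix_(p, p)][np.triu_indices(4, 1)]
            hits += stats.pearsonr(a, b).statistic >= r_obs - 1e-12
        p_exact = hits / len(perms)
        res = mantel(d1, d2, n_perm=10000, seed=9)
        se = np.sqrt(p_exact * (1 - p_exact) / 10000)
        assert abs(res.p - p_exact) <= 4 * se + 2e-4

    def test_mismatched_labels_listed(self):
        d1 = random_distance(4, 0)
        d2 = random_distance(4, 0, labels=["l0", "l1", "l2", "zz"])
        with pytest.raises(ValueError, match="zz"):
            mantel(d1, d2, n_perm=99, seed=0)

    def test_subset_identity_and_bounds(self):
        d1, d2 = random_distance(8, 10), random_distance(8, 11)
        full = mantel(d1, d2, n_perm=99, seed=3)
        same = mantel_subset(d1, d2, d1.labels, n_perm=99, seed=3)
        assert full.r == pytest.approx(same.r)
        with pytest.raises(ValueError, match=">= 4"):
            mantel_subset(d1, d2, d1.labels[:3], n_perm=99, seed=0)

    def test_subset_recomputes_on_submatrix(self):
        d1, d2 = random_distance(9, 12), random_distance(9, 13)
        labs = d1.labels[:5]
        direct = mantel(d1.submatrix(labs), d2.submatrix(labs), n_perm=99, seed=4)
        via = mantel_subset(d1, d2, labs, n_perm=99, seed=4)
        assert direct.r == pytest.approx(via.r)


class TestCooccurrence:
    def test_duplicate_and_complement_columns(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 30)
        while np.ptp(x) == 0:
            x = rng.integers(0, 2, 30)
        m = binary_catalog({"a": x, "b": x.copy(), "c": 1 - x})
        res = cooccurrence_matrix(m, n_perm=99, seed=1, traits=["a", "b", "c"])
        assert res.r.loc["a", "b"] == pytest.approx(1.0)
        assert res.r.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(res.r.values, res.r.values.T)
        np.testing.assert_allclose(np.diag(res.r.values), 1.0)

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_equals_phi_from_contingency_table(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 60)
        y = rng.integers(0, 2, 60)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            x[0], y[0] = 1 - x[0], 1 - y[0]
        m = binary_catalog({"x": x, "y": y})
        res = cooccurrence_matrix(m, n_perm=99, seed=0, traits=["x", "y"])
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        phi = (a * d - b * c) / np.sqrt(
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert res.r.loc["x", "y"] == pytest.approx(phi)

    def test_invariant_trait_is_na(self):
        m = binary_catalog({"x": [0, 1, 0, 1], "y": [1, 0, 0, 1]})
        res = cooccurrence_matrix(m, n_perm=99, seed=0, traits=["merA", "x", "y"])
        assert np.isnan(res.r.loc["merA", "x"])

    def test_needs_two_varying_traits(self):
        m = binary_catalog({"x": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="2 traits"):
            cooccurrence_matrix(m, n_perm=99, seed=0, traits=["merA"])

    def test_p_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        m = binary_catalog(
            {c: rng.integers(0, 2, 40) for c in ["a", "b", "c", "d"]}
        )
        res = cooccurrence_matrix(m, n_perm=199, seed=3, traits=["a", "b", "c", "d"])
        np.testing.assert_allclose(res.p.values, res.p.values.T)
        off = res.p.values[~np.eye(4, dtype=bool)]
        assert (off >= 1 / 200).all() and (off <= 1.0).all()


class TestBiasRegression:
    def test_no_plasmids_is_identity_line(self):
        rng = np.random.default_rng(1)
        m = binary_catalog({c: rng.integers(0, 2, 25) for c in "pqr"})
        slope, intercept, pairs = plasmid_bias_regression(m, traits=list("pqr"))
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert not pairs["plasmid_enriched"].any()

    def test_constructed_slope_two(self):
        pairs = pd.DataFrame(
            {
                "trait": list("abcd"),
                "percent_chromosome": [10.0, 20.0, 30.0, 40.0],
                "percent_all": [20.0, 40.0, 60.0, 80.0],
            }
        )
        slope, intercept, _ = bias_regression_from_pairs(pairs)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_plasmid_enriched_flagging(self):
        replicon = ["plasmid"] * 10 + ["chromosome"] * 10
        # gene q rides plasmids; gene p is chromosomal-only
        m = binary_catalog(
            {"p": [0] * 10 + [1] * 10, "q": [1] * 10 + [0] * 10},
            replicon=replicon,
        )
        _, _, pairs = plasmid_bias_regression(m, traits=["p", "q"])
        flags = pairs.set_index("trait")["plasmid_enriched"]
        assert flags["q"] and not flags["p"]

    def test_empty_chromosome_class_rejected(self):
        m = binary_catalog({"x": [0, 1, 1, 0]}, replicon=["plasmid"] * 4)
        with pytest.raises(ValueError, match="chromosomal"):
            plasmid_bias_regression(m)
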