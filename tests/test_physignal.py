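"""Blomberg's K, contrasts, and the permutation signal test."""

import numpy as np
import pandas as pd
import pytest

from merphylo import (
    CovMatrix,
    SyntheticConfig,
    TraitMatrix,
    blomberg_k,
    multi_signal,
    phylo_mean,
    pic,
    plasmid_differential,
    read_newick,
    signal_test,
    simulate_bm,
    simulate_tree,
    threshold_binary,
)


def catalog_for(taxa, traits: dict, replicon=None):
    n = len(taxa)
    df = pd.DataFrame(
        {
            "operon_id": [f"op_{t}" for t in taxa],
            "taxon_label": list(taxa),
            "genome_id": [f"g_{t}" for t in taxa],
            "replicon": replicon or ["chromosome"] * n,
            "merA": [1] * n,
            **{k: list(np.asarray(v, dtype=int)) for k, v in traits.items()},
        }
    )
    return TraitMatrix(df)


class TestPhyloMean:
    def test_identity_cov_gives_arithmetic_mean(self):
        C = CovMatrix(("a", "b", "c"), np.eye(3))
        assert phylo_mean([1.0, 2.0, 6.0], C) == pytest.approx(3.0)

    def test_symmetric_tree_block_value(self, balanced4, clade_trait4):
        from merphylo import vcv_matrix

        assert phylo_mean(clade_trait4, vcv_matrix(balanced4)) == pytest.approx(0.5)

    def test_constant_vector_invariance(self, random_chronogram):
        from merphylo import vcv_matrix

        C = vcv_matrix(random_chronogram(n_tips=9, seed=1).tree)
        assert phylo_mean(np.full(9, 3.25), C) == pytest.approx(3.25)


class TestBlombergK:
    def test_clade_pattern_closed_form(self, balanced4, clade_trait4):
        # observed MSE0/MSE = 3, Brownian expectation 5/3 -> K = 1.8
        assert blomberg_k(balanced4, clade_trait4) == pytest.approx(1.8, abs=1e-10)

    def test_anticlade_pattern_below_one(self, balanced4):
        assert blomberg_k(balanced4, np.array([0.0, 1.0, 0.0, 1.0])) < 1.0

    def test_star_tree_permutation_invariant(self):
        star = read_newick("(A:1,B:1,C:1,D:1,E:1);")
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        ks = {
            round(blomberg_k(star, x[list(p)]), 12)
            for p in [(0, 1, 2, 3, 4), (4, 3, 2, 1, 0), (2, 0, 4, 1, 3)]
        }
        assert len(ks) == 1

    def test_constant_trait_rejected(self, balanced4):
        with pytest.raises(ValueError, match="no variation"):
            blomberg_k(balanced4, np.ones(4))

    def test_too_few_tips_rejected(self):
        t = read_newick("(A:1,(B:1,C:1):1);")
        with pytest.raises(ValueError, match="4 tips"):
            blomberg_k(t, np.array([0.0, 1.0, 0.0]))

    @pytest.mark.parametrize("seed", range(10))
    def test_vcv_and_contrasts_routes_agree(self, random_chronogram, seed):
        """Two independent algorithms, one contract: agreement to 1e-10."""
        chrono = random_chronogram(n_tips=16, seed=100 + seed)
        rng = np.random.default_rng(seed)
        tree = chrono.tree
        for x in [
            rng.normal(size=16),
            threshold_binary(rng.normal(size=16), 0.4).astype(float),
        ]:
            k_vcv = blomberg_k(tree, x, method="vcv")
            k_pic = blomberg_k(tree, x, method="pic")
            assert k_vcv == pytest.approx(k_pic, abs=1e-10)


class TestPic:
    def test_two_tip_contrast(self):
        t = read_newick("(A:1,B:1);")
        c = pic(t, np.array([0.0, 1.0]))
        assert abs(c[0]) == pytest.approx(1 / np.sqrt(2))

    def test_balanced_clade_contrasts(self, balanced4, clade_trait4):
        c = sorted(np.abs(pic(balanced4, clade_trait4)))
        np.testing.assert_allclose(c, [0.0, 0.0, 1 / np.sqrt(3)], atol=1e-12)

    def test_count_is_n_minus_one(self, random_chronogram):
        tree = random_chronogram(n_tips=11, seed=8).tree
        assert len(pic(tree, np.arange(11.0))) == 10

    def test_non_binary_rejected(self):
        t = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="binary"):
            pic(t, np.array([0.0, 1.0, 2.0]))


class TestSignalTest:
    def test_clade_trait_significant(self):
        chrono = simulate_tree(SyntheticConfig(n_tips=16, seed=5))
        # perfect clade membership trait: one 8-tip clade
        from merphylo import vcv_matrix

        C = vcv_matrix(chrono.tree).values
        # build the trait from the tree's own structure: tips sharing the
        # deepest split
        split = C[0] > 0
        x = split.astype(float)
        if x.sum() < 2 or x.sum() > 14:
            pytest.skip("degenerate split")
        res = signal_test(chrono.tree, x, n_perm=999, seed=1)
        assert res.p <= 0.05

    def test_p_lower_bound(self, balanced4, clade_trait4):
        res = signal_test(balanced4, clade_trait4, n_perm=99, seed=0)
        assert res.p >= 1 / 100

    def test_deterministic_under_seed(self, random_chronogram):
        tree = random_chronogram(n_tips=12, seed=3).tree
        x = threshold_binary(np.arange(12.0), 0.5).astype(float)
        a = signal_test(tree, x, n_perm=199, seed=42)
        b = signal_test(tree, x, n_perm=199, seed=42)
        assert (a.k, a.p, a.pic_variance_obs) == (b.k, b.p, b.pic_variance_obs)

    def test_consistent_relabeling_invariance(self, random_chronogram):
        # renaming tips consistently in tree and trait changes nothing
        tree = random_chronogram(n_tips=10, seed=9).tree
        x = threshold_binary(np.arange(10.0)[::-1], 0.3).astype(float)
        res1 = signal_test(tree, x, n_perm=199, seed=7)
        renamed = tree.copy()
        for leaf in renamed.dendropy_tree.leaf_node_iter():
            leaf.taxon.label = "X_" + leaf.taxon.label
        from merphylo.treeio import Tree

        renamed = Tree(renamed.dendropy_tree)
        res2 = signal_test(renamed, x, n_perm=199, seed=7)
        assert res1.p == res2.p and res1.k == pytest.approx(res2.k)

    def test_thresholded_bm_beats_shuffled(self):
        """Vertically inherited traits show more signal than shuffled ones."""
        wins = 0
        for i in range(30):
            chrono = simulate_tree(SyntheticConfig(n_tips=32, seed=400 + i))
            x = threshold_binary(simulate_bm(chrono, 1.0, seed=i), 0.5).astype(float)
            rng = np.random.default_rng(1000 + i)
            k_true = blomberg_k(chrono.tree, x, method="pic")
            k_shuf = blomberg_k(chrono.tree, x[rng.permutation(32)], method="pic")
            wins += k_true > k_shuf
        assert wins >= 24  # >= 80% of paired replicates at this size


class TestMultiSignal:
    def test_table_reproducible_and_order_independent(self, random_chronogram):
        chrono = random_chronogram(n_tips=16, seed=6)
        taxa = chrono.tree.tip_labels
        rng = np.random.default_rng(0)
        traits = {
            "merP": threshold_binary(rng.normal(size=16), 0.5),
            "merT": threshold_binary(rng.normal(size=16), 0.3),
            "merC": threshold_binary(rng.normal(size=16), 0.6),
        }
        m1 = catalog_for(taxa, traits)
        m2 = catalog_for(taxa, dict(reversed(list(traits.items()))))
        t1 = multi_signal(chrono.tree, m1, n_perm=99, seed=11)
        t2 = multi_signal(chrono.tree, m2, n_perm=99, seed=11)
        merged = t1.set_index("trait").join(
            t2.set_index("trait"), lsuffix="_a", rsuffix="_b"
        )
        np.testing.assert_allclose(merged["K_a"], merged["K_b"])
        np.testing.assert_allclose(merged["p_a"], merged["p_b"])
        pd.testing.assert_frame_equal(
            t1, multi_signal(chrono.tree, m1, n_perm=99, seed=11)
        )

    def test_invariant_trait_reported_na(self, random_chronogram):
        chrono = random_chronogram(n_tips=8, seed=2)
        m = catalog_for(chrono.tree.tip_labels, {"merH": np.zeros(8, dtype=int)})
        table = multi_signal(chrono.tree, m, n_perm=99, seed=0)
        row = table.set_index("trait").loc["merH"]
        assert np.isnan(row["K"]) and np.isnan(row["p"])
        assert row["presence"] == 0 and row["absence"] == 8

    def test_disjoint_taxa_rejected(self, random_chronogram):
        chrono = random_chronogram(n_tips=8, seed=2)
        m = catalog_for([f"z{i}" for i in range(8)], {"merP": [0, 1] * 4})
        with pytest.raises(ValueError, match="shared"):
            multi_signal(chrono.tree, m, n_perm=99, seed=0)


class TestPlasmidDifferential:
    def test_identity_arms_give_zero_delta(self, random_chronogram):
        chrono = random_chronogram(n_tips=12, seed=14)
        taxa = chrono.tree.tip_labels
        rng = np.random.default_rng(3)
        m = catalog_for(
            taxa,
            {"merP": threshold_binary(rng.normal(size=12), 0.5)},
        )  # all chromosomal: both arms see identical data
        rep = plasmid_differential(chrono.tree, chrono.tree, m, n_perm=99, seed=5)
        varying = rep.dropna(subset=["delta_k"])
        assert len(varying) >= 1
        assert (varying["delta_k"] == 0).all()
        assert (varying["p_with"] == varying["p_without"]).all()

    def test_report_sorted_by_delta(self, random_chronogram):
        chrono = random_chronogram(n_tips=20, seed=15)
        taxa = chrono.tree.tip_labels
        rng = np.random.default_rng(4)
        replicon = ["plasmid" if i < 5 else "chromosome" for i in range(20)]
        traits = {
            f"mer{c}": threshold_binary(rng.normal(size=20), 0.5) for c in "PTC"
        }
        m = catalog_for(taxa, traits, replicon=replicon)
        from merphylo import prune

        chrom_tree = prune(chrono.tree, taxa[5:])
        rep = plasmid_differential(chrono.tree, chrom_tree, m, n_perm=99, seed=6)
        deltas = rep["delta_k"].dropna().to_numpy()
        assert (np.diff(deltas) <= 1e-12).all()
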