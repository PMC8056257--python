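import numpy as np
import pandas as pd
import pytest

from pleiocfdr import synthetic_data as sd
from pleiocfdr.expression_validation import rank_sum_test


class TestSimulateJointGwas:
    def test_same_seed_is_bit_identical(self):
        cfg = sd.SimConfig(n_snps=500, seed=11)
        a1, b1, tr1 = sd.simulate_joint_gwas(cfg)
        a2, b2, tr2 = sd.simulate_joint_gwas(sd.SimConfig(n_snps=500, seed=11))
        pd.testing.assert_frame_equal(a1.df, a2.df)
        pd.testing.assert_frame_equal(b1.df, b2.df)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_different_seed_differs(self):
        a1, _, _ = sd.simulate_joint_gwas(sd.SimConfig(n_snps=500, seed=11))
        a2, _, _ = sd.simulate_joint_gwas(sd.SimConfig(n_snps=500, seed=12))
        assert not np.array_equal(a1.df["p_value"], a2.df["p_value"])

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="fractions"):
            sd.simulate_joint_gwas(sd.SimConfig(pi=(0.9, 0.02, 0.02, 0.02)))

    def test_p_values_in_open_unit_interval(self):
        _, t2, _ = sd.simulate_joint_gwas(sd.SimConfig(n_snps=5000, sigma=8, seed=1))
        p = t2.df["p_value"]
        assert (p > 0).all() and (p <= 1).all()

    def test_all_null_p_values_uniform(self):
        t1, _, _ = sd.simulate_joint_gwas(
            sd.SimConfig(n_snps=20_000, pi=(1, 0, 0, 0), seed=2))
        rate = (t1.df["p_value"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 20_000))

    def test_traits_independent_without_pleiotropy(self):
        _, _, truth = sd.simulate_joint_gwas(
            sd.SimConfig(n_snps=50_000, pi=(0.96, 0.02, 0.02, 0.0), seed=3))
        corr = np.corrcoef(truth["z1"], truth["z2"])[0, 1]
        assert abs(corr) < 3 / np.sqrt(50_000)

    def test_component_labels_match_latent_means(self):
        _, _, truth = sd.simulate_joint_gwas(sd.SimConfig(n_snps=5000, seed=4))
        comp = truth["component"]
        assert (truth.loc[comp == "00", ["mu1", "mu2"]] == 0).all().all()
        assert (truth.loc[comp == "10", "mu2"] == 0).all()
        assert (truth.loc[comp == "11", "mu1"] != 0).all()

    def test_negative_rho_gives_opposite_direction_pleiotropy(self):
        _, _, truth = sd.simulate_joint_gwas(
            sd.SimConfig(n_snps=30_000, pi=(0.9, 0, 0, 0.1), rho=-0.9, seed=5))
        pleio = truth[truth["component"] == "11"]
        r = np.corrcoef(pleio["mu1"], pleio["mu2"])[0, 1]
        assert r < -0.85

    def test_empirical_fdp_helper(self):
        truth = pd.DataFrame({"component": ["00", "10", "01", "11"]})
        called = np.array([True, True, True, False])
        assert sd.empirical_fdp(called, truth, trait=1) == pytest.approx(2 / 3)
        assert sd.empirical_fdp(np.zeros(4, bool), truth, trait=1) == 0.0


class TestSimulateLdPanel:
    def make_snps(self, n, seed=0):
        t1, _, _ = sd.simulate_joint_gwas(sd.SimConfig(n_snps=n, seed=seed))
        return t1.df

    def test_singleton_blocks_have_no_high_ld(self):
        cfg = sd.SimConfig(n_snps=40, block_size_range=(1, 1), seed=6)
        _, ld, _ = sd.simulate_ld_panel(self.make_snps(40, 6), cfg)
        assert (ld.df["r2"] < 0.2).all()

    def test_within_block_r2_near_target(self):
        cfg = sd.SimConfig(n_snps=200, block_size_range=(2, 6),
                           within_block_r2=0.9, n_individuals=200, seed=7)
        snps = self.make_snps(200, 7)
        _, ld, block_of = sd.simulate_ld_panel(snps, cfg)
        bmap = dict(zip(snps["snp_id"], block_of))
        within = [r for a, b, r in zip(ld.df["snp_a"], ld.df["snp_b"], ld.df["r2"])
                  if bmap[a] == bmap[b]]
        assert 0.8 <= np.mean(within) <= 1.0

    def test_across_block_r2_at_independence_baseline(self):
        cfg = sd.SimConfig(n_snps=150, block_size_range=(2, 4),
                           within_block_r2=0.9, n_individuals=200, seed=8)
        snps = self.make_snps(150, 8)
        _, ld, block_of = sd.simulate_ld_panel(snps, cfg)
        bmap = dict(zip(snps["snp_id"], block_of))
        across = [r for a, b, r in zip(ld.df["snp_a"], ld.df["snp_b"], ld.df["r2"])
                  if bmap[a] != bmap[b]]
        # E[r2] for independent vectors of n individuals is ~1/(n-1)
        assert np.mean(across) == pytest.approx(1 / 199, abs=0.01)

    def test_block_size_exceeding_n_snps_error(self):
        cfg = sd.SimConfig(n_snps=5, block_size_range=(10, 10), seed=9)
        with pytest.raises(ValueError, match="block size"):
            sd.simulate_ld_panel(self.make_snps(5, 9), cfg)

    def test_deterministic(self):
        cfg = sd.SimConfig(n_snps=50, seed=10)
        snps = self.make_snps(50, 10)
        p1, ld1, _ = sd.simulate_ld_panel(snps, cfg)
        p2, ld2, _ = sd.simulate_ld_panel(snps, cfg)
        np.testing.assert_array_equal(p1.matrix, p2.matrix)
        pd.testing.assert_frame_equal(ld1.df, ld2.df)

    def test_dosages_are_genotype_counts(self):
        cfg = sd.SimConfig(n_snps=50, seed=11)
        panel, _, _ = sd.simulate_ld_panel(self.make_snps(50, 11), cfg)
        assert set(np.unique(panel.matrix)) <= {0.0, 1.0, 2.0}


class TestSimulateExpression:
    GENES = [f"G{i}" for i in range(30)]

    def test_same_seed_identical(self):
        d = sd.ExpressionDesign(effect_genes=("G1",), seed=12)
        e1, m1 = sd.simulate_expression(self.GENES, d)
        e2, m2 = sd.simulate_expression(self.GENES, d)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_group_design_sizes(self):
        expr, meta = sd.simulate_expression(self.GENES, sd.ExpressionDesign(seed=13))
        assert (meta["group"] == "young").sum() == 16
        assert (meta["group"] == "old").sum() == 12

    def test_large_shift_detected_with_high_probability(self):
        hits = 0
        for seed in range(20):
            d = sd.ExpressionDesign(effect_genes=("G0",), effect_size=2.0, seed=seed)
            expr, meta = sd.simulate_expression(self.GENES, d)
            young = expr.loc["G0", meta.index[meta["group"] == "young"]]
            old = expr.loc["G0", meta.index[meta["group"] == "old"]]
            if rank_sum_test(young, old).p_value < 0.05:
                hits += 1
        assert hits >= 18

    def test_trait_coupled_gene_correlates(self):
        d = sd.ExpressionDesign(trait_genes=("G5",), trait_r=0.8, seed=14)
        expr, meta = sd.simulate_expression(self.GENES, d)
        r = np.corrcoef(expr.loc["G5"], meta["trait"])[0, 1]
        assert r > 0.5

    def test_unknown_effect_gene_error(self):
        with pytest.raises(ValueError, match="effect genes"):
            sd.simulate_expression(self.GENES,
                                   sd.ExpressionDesign(effect_genes=("NOPE",)))

    def test_group_size_validation(self):
        with pytest.raises(ValueError, match="group sizes"):
            sd.simulate_expression(self.GENES, sd.ExpressionDesign(n_group_a=0))


class TestCatalogFromTruth:
    def test_catalog_subset_of_requested_components(self):
        cfg = sd.SimConfig(n_snps=3000, seed=15)
        t1, _, truth = sd.simulate_joint_gwas(cfg)
        cat = sd.catalog_from_truth(t1.df, truth, components=("11",), fraction=0.5, seed=15)
        labels = truth.set_index("snp_id").loc[cat["snp_id"], "component"]
        assert (labels == "11").all()
        assert 0 < len(cat) < (truth["component"] == "11").sum() + 1
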