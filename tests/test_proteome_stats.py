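import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_score
from statsmodels.stats.multitest import multipletests

from ntermflow.io_formats import AnalysisConfig
from ntermflow.proteome_stats import (
    anova_bh,
    filter_quantifiable,
    impute_missing,
    log2_transform,
    pairwise_t_flags,
    pca_coordinates,
    run_proteome_pipeline,
    tukey_hsd,
    zscore,
    zscore_cluster,
)


class TestFilterQuantifiable:
    def test_two_of_four_in_one_genotype_kept(self, quant_factory, cfg):
        row = [1.0, 2.0, np.nan, np.nan] + [np.nan] * 8
        t = filter_quantifiable(quant_factory([row]), cfg)
        assert len(t.data) == 1

    def test_one_of_four_everywhere_dropped(self, quant_factory, cfg):
        row = [1.0] + [np.nan] * 3 + [2.0] + [np.nan] * 3 + [3.0] + [np.nan] * 3
        t = filter_quantifiable(quant_factory([row]), cfg)
        assert len(t.data) == 0
        assert t.data.attrs["n_dropped"] == 1

    def test_matches_brute_force_on_random_fixture(self, quant_factory, cfg):
        rng = np.random.default_rng(8)
        vals = rng.uniform(1, 10, size=(10, 12))
        vals[rng.random(size=vals.shape) < 0.6] = np.nan
        t = quant_factory(vals)
        kept = set(filter_quantifiable(t, cfg).data.index)
        brute = {
            f"prot{i}"
            for i in range(10)
            if any(
                np.isfinite(vals[i, g * 4 : (g + 1) * 4]).sum() >= cfg.min_quant_reps
                for g in range(3)
            )
        }
        assert kept == brute

    def test_single_replicate_design_rejected(self, cfg):
        from ntermflow.io_formats import QuantTable, design_from_columns

        cols = ["wt_1", "mi_1", "mi_2"]
        t = QuantTable(
            data=pd.DataFrame([[1.0, 2.0, 3.0]], columns=cols, index=["p"]),
            design=design_from_columns(cols),
        )
        with pytest.raises(ValueError, match="wt"):
            filter_quantifiable(t, cfg)


class TestImputation:
    def test_no_missing_is_identity(self, quant_factory, cfg):
        vals = np.arange(24.0).reshape(2, 12) + 1
        t = quant_factory(vals)
        out, mask = impute_missing(t, cfg, seed=1)
        np.testing.assert_array_equal(out.matrix().to_numpy(), vals)
        assert not mask.to_numpy().any()

    def test_deterministic_given_seed(self, quant_factory, cfg):
        rng = np.random.default_rng(2)
        vals = rng.normal(20, 2, size=(50, 12))
        vals[rng.random(size=vals.shape) < 0.2] = np.nan
        t = quant_factory(vals)
        a, _ = impute_missing(t, cfg, seed=7)
        b, _ = impute_missing(t, cfg, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)
        c, _ = impute_missing(t, cfg, seed=8)
        assert not a.matrix().equals(c.matrix())

    def test_zero_width_imputes_at_downshifted_mean(self, quant_factory):
        cfg = AnalysisConfig(impute_width=1e-12, impute_downshift=1.8)
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 2, size=(200, 12))
        vals[:100, 0] = np.nan
        t = quant_factory(vals)
        out, mask = impute_missing(t, cfg, seed=1)
        obs = vals[100:, 0]
        target = obs.mean() - 1.8 * obs.std(ddof=1)
        imputed = out.matrix().to_numpy()[:100, 0]
        np.testing.assert_allclose(imputed, target, atol=1e-6)

    def test_imputed_distribution_matches_downshifted_gaussian(self, quant_factory, cfg):
        rng = np.random.default_rng(4)
        n = 2000
        vals = rng.normal(20, 2, size=(n, 12))
        missing = rng.random(size=n) < 0.5
        vals[missing, 0] = np.nan
        t = quant_factory(vals)
        out, mask = impute_missing(t, cfg, seed=5)
        obs = vals[~missing, 0]
        mu_t = obs.mean() - cfg.impute_downshift * obs.std(ddof=1)
        sd_t = cfg.impute_width * obs.std(ddof=1)
        imput = out.matrix().to_numpy()[missing, 0]
        se = sd_t / np.sqrt(imput.size)
        assert abs(imput.mean() - mu_t) < 3 * se

    def test_sparse_sample_falls_back_to_global(self, quant_factory, cfg, caplog):
        vals = np.full((5, 12), 20.0)
        vals[:, 0] = np.nan
        vals[0, 0] = 21.0  # single observed value in wt_1
        t = quant_factory(vals)
        with caplog.at_level("WARNING"):
            out, _ = impute_missing(t, cfg, seed=1)
        assert "wt_1" in caplog.text
        assert np.isfinite(out.matrix().to_numpy()).all()


class TestAnovaBH:
    def test_bh_matches_brute_force_and_statsmodels(self, quant_factory, cfg):
        rng = np.random.default_rng(6)
        vals = rng.normal(20, 1, size=(20, 12))
        vals[:5, 8:] += 3  # real effects in ox
        t = quant_factory(vals)
        res = anova_bh(t, cfg)
        # reference q-values
        ref_q = multipletests(res["anova_p"], method="fdr_bh")[1]
        np.testing.assert_allclose(res["anova_q"], ref_q, rtol=1e-12)
        # brute-force BH decision over all cutoffs
        p = res["anova_p"].to_numpy()
        m = p.size
        thresh = 0.0
        for k in range(m, 0, -1):
            pk = np.sort(p)[k - 1]
            if pk <= k / m * cfg.fdr_q:
                thresh = pk
                break
        np.testing.assert_array_equal(res["significant"], p <= thresh)

    def test_four_small_pvalues_all_pass(self, cfg):
        # direct BH arithmetic: (0.01,0.02,0.03,0.04) with m=4, q=0.05
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert (q < cfg.fdr_q).all()

    def test_anova_p_matches_scipy_per_row(self, quant_factory, cfg):
        rng = np.random.default_rng(13)
        vals = rng.normal(0, 1, size=(10, 12))
        res = anova_bh(quant_factory(vals), cfg)
        for i in range(10):
            ref = stats.f_oneway(vals[i, :4], vals[i, 4:8], vals[i, 8:])
            assert res["anova_p"].iloc[i] == pytest.approx(ref.pvalue)

    def test_q_monotone_in_p(self, quant_factory, cfg):
        rng = np.random.default_rng(14)
        res = anova_bh(quant_factory(rng.normal(0, 1, size=(100, 12))), cfg)
        s = res.sort_values("anova_p")
        assert (np.diff(s["anova_q"]) >= -1e-15).all()

    def test_null_simulation_controls_fdr(self, quant_factory, cfg):
        rng = np.random.default_rng(20)
        m = 10_000
        res = anova_bh(quant_factory(rng.normal(20, 1, size=(m, 12))), cfg)
        frac = res["significant"].mean()
        se = np.sqrt(cfg.fdr_q * (1 - cfg.fdr_q) / m)
        assert frac <= cfg.fdr_q + 3 * se


class TestTukey:
    def test_separated_group_flagged(self, quant_factory, cfg):
        vals = np.array([[0, 0, 0, 0, 0.01, -0.01, 0, 0, 5, 5, 5.01, 4.99]])
        t = quant_factory(vals)
        res = tukey_hsd(t, ["prot0"], cfg)
        assert not res["tukey_flag_wt_vs_mi"].iloc[0]
        assert res["tukey_flag_wt_vs_ox"].iloc[0]
        assert res["tukey_flag_mi_vs_ox"].iloc[0]

    def test_critical_value_matches_published_table(self, cfg):
        # q(0.05; k=3, df=9) = 3.95 in standard studentized-range tables
        q = stats.studentized_range.isf(0.05, 3, 9)
        assert q == pytest.approx(3.95, abs=0.01)

    def test_flags_agree_with_scipy_tukey(self, quant_factory, cfg):
        rng = np.random.default_rng(15)
        vals = rng.normal(0, 1, size=(20, 12))
        vals[:8, 8:] += rng.uniform(1, 3, size=(8, 1))
        t = quant_factory(vals)
        res = tukey_hsd(t, t.data.index, cfg)
        for i in range(20):
            ref = stats.tukey_hsd(vals[i, :4], vals[i, 4:8], vals[i, 8:])
            assert bool(res["tukey_flag_wt_vs_mi"].iloc[i]) == (ref.pvalue[0, 1] < 0.05)
            assert bool(res["tukey_flag_wt_vs_ox"].iloc[i]) == (ref.pvalue[0, 2] < 0.05)
            assert bool(res["tukey_flag_mi_vs_ox"].iloc[i]) == (ref.pvalue[1, 2] < 0.05)

    def test_family_wise_error_near_alpha(self, quant_factory, cfg):
        """Null triplets: probability of any flagged pair ~ alpha."""
        rng = np.random.default_rng(30)
        m = 10_000
        t = quant_factory(rng.normal(0, 1, size=(m, 12)))
        res = tukey_hsd(t, t.data.index, cfg)
        any_flag = res[[c for c in res.columns if c.startswith("tukey_flag")]].any(axis=1)
        assert any_flag.mean() == pytest.approx(0.05, abs=0.01)


class TestPairwiseT:
    def test_identical_groups_unflagged(self, quant_factory, cfg):
        vals = np.tile(np.array([5.0, 5.1, 4.9, 5.0]), (1, 3))
        res = pairwise_t_flags(quant_factory(vals), cfg)
        assert not res.filter(like="t_flag").to_numpy().any()

    def test_huge_separation_flagged(self, quant_factory, cfg):
        vals = np.array([[0, 0.1, -0.1, 0, 10, 10.1, 9.9, 10, 0, 0.1, -0.1, 0]])
        res = pairwise_t_flags(quant_factory(vals), cfg)
        assert res["t_flag_wt_vs_mi"].iloc[0]
        assert not res["t_flag_wt_vs_ox"].iloc[0]

    def test_matches_scipy_pooled(self, quant_factory, cfg):
        rng = np.random.default_rng(16)
        vals = rng.normal(0, 1, size=(15, 12))
        res = pairwise_t_flags(quant_factory(vals), cfg)
        for i in range(15):
            ref = stats.ttest_ind(vals[i, :4], vals[i, 4:8], equal_var=True)
            assert res["t_p_wt_vs_mi"].iloc[i] == pytest.approx(ref.pvalue)

    def test_null_type_i_near_alpha(self, quant_factory, cfg):
        rng = np.random.default_rng(17)
        res = pairwise_t_flags(quant_factory(rng.normal(0, 1, size=(5000, 12))), cfg)
        frac = res["t_flag_wt_vs_mi"].mean()
        assert frac == pytest.approx(0.05, abs=0.01)


class TestClustering:
    def test_zscore_rows_standardized(self, quant_factory):
        rng = np.random.default_rng(18)
        t = quant_factory(rng.normal(20, 3, size=(10, 12)))
        z = zscore(t, t.data.index)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_two_archetypes_recovered_exactly(self, quant_factory):
        cfg = AnalysisConfig(n_clusters_k=2)
        rng = np.random.default_rng(19)
        up_in_ox = np.array([0.0] * 8 + [5.0] * 4)
        up_in_mi = np.array([0.0] * 4 + [5.0] * 4 + [0.0] * 4)
        vals = np.vstack(
            [up_in_ox + rng.normal(0, 0.05, 12) for _ in range(30)]
            + [up_in_mi + rng.normal(0, 0.05, 12) for _ in range(20)]
        )
        t = quant_factory(vals)
        ids, profiles = zscore_cluster(t, t.data.index, cfg)
        truth = [0] * 30 + [1] * 20
        assert adjusted_rand_score(truth, ids) == 1.0
        assert len(profiles) == 2

    def test_k1_single_cluster(self, quant_factory):
        cfg = AnalysisConfig(n_clusters_k=1)
        rng = np.random.default_rng(21)
        t = quant_factory(rng.normal(0, 1, size=(7, 12)))
        ids, profiles = zscore_cluster(t, t.data.index, cfg)
        assert set(ids) == {1}

    def test_cluster_sizes_sum_to_significant_set(self, quant_factory, cfg):
        rng = np.random.default_rng(22)
        t = quant_factory(rng.normal(0, 1, size=(40, 12)))
        sig = t.data.index[:25]
        ids, _ = zscore_cluster(t, sig, cfg)
        assert len(ids) == 25
        assert ids.value_counts().sum() == 25


class TestPCA:
    def test_identical_samples_give_equal_scores(self, quant_factory):
        vals = np.tile(np.arange(10.0).reshape(-1, 1), (1, 12))
        t = quant_factory(vals)
        scores, evr = pca_coordinates(t, t.data.index)
        assert np.allclose(scores[["PC1", "PC2"]].to_numpy(), 0, atol=1e-6)

    def test_genotypes_separate_with_effects(self, quant_factory):
        rng = np.random.default_rng(24)
        base = rng.normal(0, 0.1, size=(50, 12))
        base[:20, 4:8] += 3
        base[20:40, 8:] += 3
        t = quant_factory(base)
        scores, evr = pca_coordinates(t, t.data.index)
        labels = scores["genotype"]
        sil = silhouette_score(scores[["PC1", "PC2"]], labels)
        assert sil > 0
        assert (np.diff(evr) <= 1e-12).all()


class TestPipeline:
    def test_conservation_and_determinism(self, quant_factory):
        cfg = AnalysisConfig(rng_seed=11, n_clusters_k=3)
        rng = np.random.default_rng(25)
        vals = 2.0 ** rng.normal(20, 2, size=(60, 12))
        vals[:20, 8:] *= 4  # effects in ox
        vals[rng.random(size=vals.shape) < 0.1] = np.nan
        t = quant_factory(vals)
        res1 = run_proteome_pipeline(t, cfg, seed=11)
        res2 = run_proteome_pipeline(t, cfg, seed=11)
        pd.testing.assert_frame_equal(res1.to_frame(), res2.to_frame())
        # every input protein is dropped or tested; tested ones have p and q
        n_dropped = res1.filtered.data.attrs["n_dropped"]
        assert n_dropped + len(res1.anova) == 60
        assert res1.anova[["anova_p", "anova_q"]].notna().all().all()
        assert (res1.anova["anova_q"] >= res1.anova["anova_p"] - 1e-15).all()

    def test_no_missing_results_seed_independent(self, quant_factory, cfg):
        rng = np.random.default_rng(26)
        vals = 2.0 ** rng.normal(20, 2, size=(30, 12))
        t = quant_factory(vals)
        a = run_proteome_pipeline(t, cfg, seed=1)
        b = run_proteome_pipeline(t, cfg, seed=2)
        pd.testing.assert_frame_equal(a.anova, b.anova)
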