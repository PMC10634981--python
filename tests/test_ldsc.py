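"""LD score regression: heritability, genetic correlation, liability
conversion, jackknife behaviour and stratified enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pleiofactor as pf
from pleiofactor.ldsc import _jackknife_wls

from conftest import make_sumstats


class TestLDScores:
    def test_identity_ld_gives_unit_scores(self):
        cfg = pf.SimConfig(n_blocks=5, snps_per_block=10, rho_ld=0.0, seed=1,
                           n_overlap=0, pheno_corr_overlap=0.0,
                           var_factor=0.1, var_unique_1=0.0, var_unique_2=0.0,
                           s_sel=0.0, n1=10_000, n2=10_000)
        panel = pf.simulate_ld_panel(cfg)
        ld = pf.compute_ld_scores(panel)
        assert np.allclose(ld["l2"], 1.0)

    def test_all_snps_annotation_matches_total(self, mixed_study):
        panel = mixed_study["panel"]
        A = np.ones((len(panel), 1), dtype=int)
        ld = pf.compute_ld_scores(panel, A)
        assert np.allclose(ld["l2_anno0"], ld["l2"])


class TestFitH2:
    def test_all_chi2_one_gives_null_h2_unit_intercept(self):
        rng = np.random.default_rng(0)
        n = 2000
        df = pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(n)],
                "chrom": 1,
                "pos": np.arange(n) * 1000 + 1,
                "a1": "A",
                "a2": "G",
                "eaf": 0.3,
                "z": 1.0,
                "se": 0.01,
                "n": 10_000,
            }
        )
        df["beta"] = df["z"] * df["se"]
        ss = pf.SummaryStats(df)
        ld = pd.DataFrame({"snp": df["snp"], "l2": rng.uniform(1, 10, n)})
        est = pf.fit_h2(ss, ld, n_blocks_jk=20)
        assert est.h2_obs == pytest.approx(0.0, abs=1e-9)
        assert est.intercept == pytest.approx(1.0, abs=1e-9)

    def test_recovery_within_two_jackknife_se(self, mixed_study):
        d = mixed_study
        est = pf.fit_h2(d["s1"], d["ld"])
        assert abs(est.h2_obs - 0.20) < 2 * est.se_obs
        assert est.se_obs > 0

    def test_doubling_n_halves_h2(self, mixed_study):
        d = mixed_study
        est1 = pf.fit_h2(d["s1"], d["ld"])
        df2 = d["s1"].df.copy()
        df2["n"] = df2["n"] * 2
        est2 = pf.fit_h2(pf.SummaryStats(df2), d["ld"])
        assert est2.h2_obs == pytest.approx(est1.h2_obs / 2, rel=1e-9)

    def test_too_few_snps_fatal(self, mixed_study):
        small = pf.SummaryStats(mixed_study["s1"].df.head(100))
        with pytest.raises(ValueError):
            pf.fit_h2(small, mixed_study["ld"])

    def test_liability_fields_present_iff_prevalences(self, mixed_study):
        d = mixed_study
        obs = pf.fit_h2(d["s1"], d["ld"])
        assert obs.h2_liab is None
        liab = pf.fit_h2(d["s1"], d["ld"], K=0.05, P=0.045)
        assert liab.h2_liab == pytest.approx(
            liab.h2_obs * pf.liability_multiplier(0.05, 0.045))


class TestLiability:
    def test_zero_maps_to_zero(self):
        assert pf.obs_to_liability(0.0, 0.05, 0.045) == 0.0

    def test_dyslexia_prevalence_multiplier(self):
        # K=0.050, P=0.045: multiplier ~ 4.94
        assert pf.liability_multiplier(0.050, 0.045) == pytest.approx(4.94, abs=0.01)

    def test_balanced_case_closed_form(self):
        # K=P=0.5: (1/16) / (1/4 * phi(0)^2) = pi/2
        assert pf.liability_multiplier(0.5, 0.5) == pytest.approx(np.pi / 2, rel=1e-12)

    def test_linear_in_h2_obs(self):
        m = pf.obs_to_liability(0.1, 0.02, 0.3) / 0.1
        assert pf.obs_to_liability(0.37, 0.02, 0.3) == pytest.approx(0.37 * m)

    def test_invalid_prevalence_fatal(self):
        with pytest.raises(ValueError):
            pf.obs_to_liability(0.1, 0.0, 0.5)


class TestGeneticCorrelation:
    def test_self_correlation_is_exactly_one(self, mixed_study):
        d = mixed_study
        est = pf.fit_rg(d["s1"], d["s1"], d["ld"])
        uni = pf.fit_h2(d["s1"], d["ld"])
        assert est.rg == pytest.approx(1.0, abs=1e-12)
        assert est.S[0, 1] == pytest.approx(uni.h2_obs, abs=1e-12)

    def test_recovery_within_two_se(self, mixed_study):
        d = mixed_study
        est = pf.fit_rg(d["s1"], d["s2"], d["ld"])
        assert abs(est.rg - d["cfg"].rg_true) < 2 * est.se_rg

    def test_null_overlap_intercept(self):
        cfg = pf.SimConfig(n_blocks=400, snps_per_block=50, seed=31,
                           var_factor=0.0, var_unique_1=0.0, var_unique_2=0.0,
                           s_sel=0.0, n1=50_000, n2=50_000,
                           n_overlap=50_000, pheno_corr_overlap=0.3)
        panel, _, a, b = pf.simulate_study(cfg)
        ld = pf.compute_ld_scores(panel)
        est = pf.multivariable_ldsc(a, b, ld)
        assert est.intercepts[0, 1] == pytest.approx(0.3, abs=0.05)
        assert abs(est.S[0, 1]) < 0.02  # slope ~ 0 under the null

    def test_v_diagonal_matches_jackknife_se(self, mixed_study):
        d = mixed_study
        est = pf.multivariable_ldsc(d["s1"], d["s2"], d["ld"])
        h1 = pf.fit_h2(d["s1"], d["ld"])
        assert est.V[0, 0] == pytest.approx(h1.se_obs ** 2, rel=1e-9)
        assert np.allclose(est.V, est.V.T)
        assert np.linalg.eigvalsh(est.V).min() > -1e-12

    def test_v_cross_term_small_for_independent_traits(self):
        # disjoint samples, independent architectures: Cov(S11, S22) ~ 0
        cfg = pf.SimConfig(n_blocks=400, snps_per_block=50, seed=37,
                           var_factor=0.0, var_unique_1=0.2, var_unique_2=0.2,
                           s_sel=0.0, n1=50_000, n2=50_000,
                           n_overlap=0, pheno_corr_overlap=0.0)
        panel, _, a, b = pf.simulate_study(cfg)
        ld = pf.compute_ld_scores(panel)
        est = pf.multivariable_ldsc(a, b, ld)
        scale = np.sqrt(est.V[0, 0] * est.V[2, 2])
        assert abs(est.V[0, 2]) < 0.5 * scale


class TestJackknife:
    def test_matches_analytic_ols_se_under_homoskedastic_null(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.uniform(1, 10, n)
        y = 1.0 + rng.normal(0, 1, n)  # slope 0, iid noise
        X = np.column_stack([np.ones(n), x])
        theta, cov, _ = _jackknife_wls(X, y, np.ones(n), 100)
        resid = y - X @ theta
        s2 = resid @ resid / (n - 2)
        cov_ols = s2 * np.linalg.inv(X.T @ X)
        for i in (0, 1):
            ratio = np.sqrt(cov[i, i] / cov_ols[i, i])
            assert 0.8 < ratio < 1.2

    def test_more_blocks_than_snps_fatal(self):
        X = np.ones((10, 1))
        with pytest.raises(ValueError):
            _jackknife_wls(X, np.ones(10), np.ones(10), 20)


class TestStratified:
    def test_single_base_annotation_enrichment_exactly_one(self, mixed_study):
        d = mixed_study
        A = np.ones((len(d["panel"]), 1), dtype=int)
        ld = pf.compute_ld_scores(d["panel"], A)
        res = pf.stratified_h2(d["s1"], ld, A)
        assert res.table.loc[0, "enrichment"] == 1.0
        assert res.table.loc[0, "prop_h2"] == 1.0

    def test_partition_prop_h2_sums_to_one(self, mixed_study):
        d = mixed_study
        panel = d["panel"]
        M = len(panel)
        rng = np.random.default_rng(7)
        part = rng.integers(0, 2, M)
        # base + two disjoint annotations partitioning the genome
        A = np.column_stack([np.ones(M, dtype=int), part, 1 - part])
        ld = pf.compute_ld_scores(panel, A)
        res = pf.stratified_h2(d["s1"], ld, A,
                               annotation_names=["base", "half1", "half2"])
        assert res.table.loc[1:, "prop_h2"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_enrichment_recovery(self, mixed_study):
        d = mixed_study
        anno, info = pf.simulate_annotation(d["panel"], d["truth"], 0.1, 1.0, seed=11)
        A = np.column_stack([np.ones(len(d["panel"]), dtype=int), anno])
        ld = pf.compute_ld_scores(d["panel"], A)
        res = pf.stratified_h2(d["s1"], ld, A)
        row = res.table.iloc[1]
        expected = info["expected_enrichment_trait1"]
        assert abs(row["enrichment"] - expected) < 2 * row["se_enrichment"]

    def test_depleted_annotation_below_one(self, mixed_study):
        d = mixed_study
        anno, _ = pf.simulate_annotation(d["panel"], d["truth"], 0.2, 0.0, seed=13)
        A = np.column_stack([np.ones(len(d["panel"]), dtype=int), anno])
        ld = pf.compute_ld_scores(d["panel"], A)
        res = pf.stratified_h2(d["s1"], ld, A)
        assert res.table.iloc[1]["enrichment"] < 1.0

    def test_collinear_annotation_dropped(self, mixed_study):
        d = mixed_study
        M = len(d["panel"])
        anno = np.zeros(M, dtype=int)
        anno[: M // 4] = 1
        A = np.column_stack([np.ones(M, dtype=int), anno, anno])  # duplicate
        ld = pf.compute_ld_scores(d["panel"], A)
        res = pf.stratified_h2(d["s1"], ld, A,
                               annotation_names=["base", "a", "a_copy"])
        # duplicate column is not fitted directly (tau undefined) but its
        # heritability share is still reported and matches the original
        assert list(res.table["annotation"]) == ["base", "a", "a_copy"]
        assert np.isnan(res.table.loc[2, "tau"])
        assert res.table.loc[2, "enrichment"] == pytest.approx(
            res.table.loc[1, "enrichment"])

    def test_missing_base_rejected(self, mixed_study):
        d = mixed_study
        M = len(d["panel"])
        A = np.zeros((M, 1), dtype=int)
        ld = pf.compute_ld_scores(d["panel"], np.ones((M, 1), dtype=int))
        with pytest.raises(ValueError):
            pf.stratified_h2(d["s1"], ld, A)
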