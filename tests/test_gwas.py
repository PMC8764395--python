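"""SNP-effect back-solving, PEV p-values, thresholds, inflation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import ssgwas as s
from ssgwas.config import SimConfig

from conftest import make_geno


def snp_blup_toy(seed=7, n=40, m=120):
    """Fully genotyped unrelated founders with external-frequency centering,
    so G0 is nonsingular and back-solve can be compared with SNP-BLUP."""
    cfg = SimConfig(n_founders=n, n_generations=0, n_chromosomes=2,
                    snps_per_chromosome=m // 2, seed=seed, prop_genotyped=1.0,
                    sex_limited=False, n_qtl=max(2, m // 6), h2_true=0.5,
                    fixed_effect_levels=(3, 1, 1))
    ped = s.simulate_pedigree(cfg)
    geno = s.simulate_genotypes(ped, cfg)
    pheno, truth = s.simulate_phenotypes(ped, geno, cfg)
    p_ext = np.full(geno.n_snps, 0.35)
    g0 = s.build_g(geno, freqs=p_ext)
    M = s.centered_m(geno, freqs=p_ext)
    return ped, geno, pheno, g0, M


class TestBacksolve:
    def test_zero_breeding_values_zero_effects(self):
        _, geno, _, g0, M = snp_blup_toy()
        g_hat = s.backsolve_snp_effects(M, g0.scale, g0.values,
                                        np.zeros(M.shape[0]))
        np.testing.assert_allclose(g_hat, 0.0)

    def test_linearity_in_lambda(self):
        _, geno, pheno, g0, M = snp_blup_toy()
        a22 = pheno["y"].values - pheno["y"].mean()
        g1 = s.backsolve_snp_effects(M, g0.scale, g0.values, a22, lam=1.0)
        g2 = s.backsolve_snp_effects(M, g0.scale, g0.values, a22, lam=2.0)
        np.testing.assert_allclose(g2, 2.0 * g1)

    def test_equals_snp_blup_oracle(self):
        """Unblended, untuned, fully genotyped: the back-solve reproduces the
        ridge (SNP-BLUP) solution computed from the marker model directly."""
        ped, geno, pheno, g0, M = snp_blup_toy()
        sa2, se2 = 0.5, 0.5
        Ginv = np.linalg.inv(g0.values)
        spec = s.make_model_spec(pheno, "y", sp.csr_matrix(Ginv),
                                 ped["animal"].values,
                                 genotyped_ids=geno.animal_ids,
                                 sigma_a2=sa2, sigma_e2=se2)
        sol = s.solve_mme(spec, want_c22=False)
        g_hat = s.backsolve_snp_effects(M, g0.scale, g0.values, sol.a22_hat)
        sg2 = sa2 / g0.scale
        V = M @ M.T * sg2 + np.eye(len(ped)) * se2
        Vi = np.linalg.inv(V)
        X = spec.X
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ spec.y)
        g_oracle = sg2 * M.T @ Vi @ (spec.y - X @ b)
        assert np.abs(g_hat - g_oracle).max() < 1e-6

    def test_fitted_effects_track_breeding_values(self):
        ped, geno, pheno, g0, M = snp_blup_toy()
        Ginv = np.linalg.inv(g0.values)
        spec = s.make_model_spec(pheno, "y", sp.csr_matrix(Ginv),
                                 ped["animal"].values,
                                 genotyped_ids=geno.animal_ids,
                                 sigma_a2=0.5, sigma_e2=0.5)
        sol = s.solve_mme(spec, want_c22=False)
        g_hat = s.backsolve_snp_effects(M, g0.scale, g0.values, sol.a22_hat)
        fitted = M @ g_hat
        r = np.corrcoef(fitted, sol.a22_hat - sol.a22_hat.mean())[0, 1]
        assert r > 0.99


class TestPev:
    def test_no_information_gives_zero_variance(self):
        _, geno, _, g0, M = snp_blup_toy()
        sd = s.snp_effect_pev(M, g0.scale, g0.values,
                              C22=g0.values * 0.5, sigma_a2=0.5)
        np.testing.assert_allclose(sd, 0.0, atol=1e-8)

    def test_perfect_knowledge_hand_algebra(self):
        # two animals, two SNPs: C22 = 0, Var(g) = c^2 M'G^-1 G sa2 G^-1 M
        calls = np.array([[0, 1], [2, 1]])
        g = make_geno(calls)
        p = np.array([0.4, 0.25])
        g0 = s.build_g(g, freqs=p)
        M = s.centered_m(g, freqs=p)
        sa2 = 0.7
        sd = s.snp_effect_pev(M, g0.scale, g0.values, C22=np.zeros((2, 2)),
                              sigma_a2=sa2)
        c = 1.0 / g0.scale
        expected = c ** 2 * np.diag(
            M.T @ np.linalg.inv(g0.values) @ (g0.values * sa2)
            @ np.linalg.inv(g0.values) @ M)
        np.testing.assert_allclose(sd ** 2, expected, atol=1e-12)

    def test_matches_monte_carlo_sampling_variance(self):
        """Analytic PEV diagonal vs brute-force sampling of a22_hat draws."""
        rng = np.random.default_rng(0)
        _, geno, pheno, g0, M = snp_blup_toy(n=25, m=60)
        n = M.shape[0]
        sa2 = 0.5
        C22 = g0.values * sa2 * 0.4            # PSD, below the prior variance
        cov = g0.values * sa2 - C22
        sd = s.snp_effect_pev(M, g0.scale, g0.values, C22, sa2)
        draws = rng.multivariate_normal(np.zeros(n), cov, size=5000,
                                        method="cholesky")
        g_draws = (M.T @ np.linalg.solve(g0.values, draws.T)) / g0.scale
        mc_var = g_draws.var(axis=1)
        ok = sd ** 2 > 1e-12
        assert np.abs(mc_var[ok] / sd[ok] ** 2 - 1).max() < 0.12

    def test_scale_mismatch_raises(self):
        _, geno, _, g0, M = snp_blup_toy()
        with pytest.raises(ValueError, match="scale"):
            s.snp_effect_pev(M, g0.scale, g0.values,
                             C22=g0.values * 2.0, sigma_a2=0.5)


class TestPvalues:
    @pytest.mark.parametrize("z, p", [(1.96, 0.05), (0.0, 1.0), (3.0, 0.0027)])
    def test_normal_quantiles(self, z, p):
        out = s.snp_pvalues(np.array([z]), np.array([1.0]))
        assert out[0] == pytest.approx(p, abs=5e-4)

    def test_zero_sd_reported_as_nan(self):
        out = s.snp_pvalues(np.array([1.0, 2.0]), np.array([1.0, 0.0]))
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_comonotone_with_z(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=50)
        sd = rng.uniform(0.5, 2.0, size=50)
        p = s.snp_pvalues(z, sd)
        order_z = np.argsort(-np.abs(z / sd))
        order_p = np.argsort(p)
        np.testing.assert_array_equal(order_z, order_p)


class TestVarianceExplained:
    def test_zero_effect(self):
        assert s.variance_explained(np.zeros(3), np.full(3, 0.3), 1.0).sum() == 0

    def test_arithmetic(self):
        # p = 0.5, g^2 = sigma_a2: 100 * 2*0.25 = 50%
        out = s.variance_explained(np.array([1.0]), np.array([0.5]), 1.0)
        assert out[0] == pytest.approx(50.0)

    def test_sums_to_total_for_independent_genic_trait(self):
        cfg = SimConfig(n_founders=500, n_generations=0, n_chromosomes=1,
                        snps_per_chromosome=100, ld_decay_bp=1.0, seed=4,
                        sex_limited=False, n_qtl=100, h2_true=0.5)
        ped = s.simulate_pedigree(cfg)
        geno = s.simulate_genotypes(ped, cfg)
        _, truth = s.simulate_phenotypes(ped, geno, cfg)
        order = {sid: i for i, sid in enumerate(geno.snp_map["snp_id"])}
        idx = [order[q] for q in truth.qtl_ids]
        p = geno.allele_freq()[idx]
        pct = s.variance_explained(truth.qtl_effects, p, truth.sigma_a2_true)
        assert pct.sum() == pytest.approx(100.0, abs=12.0)


class TestEffectiveTests:
    def test_identity_correlation(self):
        assert s.effective_tests(np.eye(20)) == pytest.approx(20.0)

    def test_fully_correlated_block(self):
        m = 6
        assert s.effective_tests(np.ones((m, m))) == pytest.approx(1.0)

    def test_matches_direct_eigen_formula(self):
        rng = np.random.default_rng(6)
        B = rng.standard_normal((200, 50))
        corr = np.corrcoef(B, rowvar=False)
        lam = np.linalg.eigvalsh(corr)
        oracle = sum((1.0 if x >= 1 else 0.0) + (x - np.floor(x))
                     for x in np.clip(lam, 0, None))
        assert s.effective_tests(corr) == pytest.approx(oracle, abs=1e-8)

    def test_genotype_input_bounded_by_snp_count(self, small_herd):
        geno = small_herd["geno"]
        m_eff = s.effective_tests(geno)
        assert 1.0 <= m_eff <= geno.n_snps


class TestThresholds:
    def test_study_scale_effective_tests(self):
        thr = s.thresholds(17_766, alpha=0.05)
        assert thr.significant_logp == pytest.approx(5.55, abs=0.005)
        assert thr.suggestive_p == pytest.approx(5.629e-5, rel=5e-4)

    def test_single_test(self):
        thr = s.thresholds(1, alpha=0.05)
        assert thr.significant_logp == pytest.approx(1.301, abs=1e-3)

    def test_alpha10_mode(self):
        thr = s.thresholds(100, suggestive_mode="alpha10")
        assert thr.suggestive_p == pytest.approx(1e-3)


class TestInflation:
    def test_uniform_null(self):
        rng = np.random.default_rng(8)
        lam = s.inflation_factor(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_constant_half(self):
        assert s.inflation_factor(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_doubled_chi_square(self):
        rng = np.random.default_rng(9)
        chi = stats.chi2.rvs(df=1, size=100_000, random_state=rng)
        p = stats.chi2.sf(2.0 * chi, df=1)
        assert s.inflation_factor(p) == pytest.approx(2.0, abs=0.1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            s.inflation_factor(np.array([0.5, 0.0] * 100))


class TestTables:
    def _results(self, ps):
        m = len(ps)
        return pd.DataFrame({"snp_id": [f"s{i}" for i in range(m)],
                             "chrom": 1, "pos_bp": np.arange(m) * 1000 + 1,
                             "p": ps})

    def test_no_hits(self):
        thr = s.thresholds(100)
        manhattan, qq, hits = s.gwas_tables(self._results([0.5, 0.9, 0.2]), thr)
        assert hits.empty and len(manhattan) == 3 and len(qq) == 3

    def test_boundary_p_counts_as_significant(self):
        thr = s.thresholds(100, alpha=0.05)
        res = self._results([thr.significant_p, 0.5])
        manhattan, _, hits = s.gwas_tables(res, thr)
        assert manhattan["class"].iloc[0] == "significant"

    def test_suggestive_class(self):
        thr = s.thresholds(100, alpha=0.05)
        res = self._results([thr.suggestive_p * 0.9, 0.5])
        manhattan, _, _ = s.gwas_tables(res, thr)
        assert manhattan["class"].iloc[0] == "suggestive"
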