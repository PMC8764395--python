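"""Mixed-model equations and AI-REML variance components."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ssgwas as s
from ssgwas.config import SimConfig

from conftest import pedigree_mixed_model


def gls_oracle(y, X, K_obs, sigma_a2, sigma_e2, Z_full=None, K_full=None,
               rec_idx=None):
    """Generic constrained GLS mixed-model oracle via direct covariance
    inversion: V = Z K Z' sa2 + I se2."""
    V = K_obs * sigma_a2 + np.eye(len(y)) * sigma_e2
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ b
    if K_full is not None:
        a = sigma_a2 * K_full[:, rec_idx] @ (Vi @ resid)
    else:
        a = sigma_a2 * K_obs @ (Vi @ resid)
    return b, a


class TestMme:
    def test_single_record_closed_form(self):
        # mean + one animal, K = I, ratio k: [[1,1],[1,1+k]] [b,a] = [y,y]
        spec = s.MixedModelSpec(y=np.array([3.0]), X=np.ones((1, 1)),
                                record_animal_idx=np.array([0]), n_animals=1,
                                kinv=sp.eye(1).tocsr(), sigma_a2=1.0, sigma_e2=2.0)
        lhs, rhs = s.build_mme(spec)
        np.testing.assert_allclose(lhs, [[1, 1], [1, 3]])
        sol = s.solve_mme(spec, want_c22=False)
        assert sol.b_hat[0] == pytest.approx(3.0)
        assert sol.a_hat[0] == pytest.approx(0.0)

    def test_lhs_symmetric(self, small_herd):
        spec = pedigree_mixed_model(small_herd["ped"], small_herd["pheno"])
        spec.kinv = sp.csr_matrix(np.linalg.inv(spec.K))
        spec.sigma_a2, spec.sigma_e2 = 0.4, 0.6
        lhs, _ = s.build_mme(spec)
        np.testing.assert_allclose(lhs, lhs.T, atol=1e-10)

    def test_constant_records_put_mean_in_fixed_effect(self):
        y = np.full(4, 7.0)
        spec = s.MixedModelSpec(y=y, X=np.ones((4, 1)),
                                record_animal_idx=np.arange(4), n_animals=4,
                                kinv=sp.eye(4).tocsr(), sigma_a2=1.0, sigma_e2=1.0)
        sol = s.solve_mme(spec, want_c22=False)
        assert sol.b_hat[0] == pytest.approx(7.0)
        np.testing.assert_allclose(sol.a_hat, 0.0, atol=1e-10)

    def test_vanishing_genetic_variance_shrinks_to_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=6)
        spec = s.MixedModelSpec(y=y, X=np.ones((6, 1)),
                                record_animal_idx=np.arange(6), n_animals=6,
                                kinv=sp.eye(6).tocsr(), sigma_a2=1e-10, sigma_e2=1.0)
        sol = s.solve_mme(spec, want_c22=False)
        np.testing.assert_allclose(sol.a_hat, 0.0, atol=1e-6)

    def test_matches_gls_oracle(self, small_herd):
        ped, pheno = small_herd["ped"], small_herd["pheno"]
        spec = pedigree_mixed_model(ped, pheno)
        spec.kinv = sp.csr_matrix(np.linalg.inv(spec.K))
        spec.sigma_a2, spec.sigma_e2 = 0.4, 0.6
        sol = s.solve_mme(spec, want_c22=False)
        idx = spec.record_animal_idx
        K_obs = spec.K[np.ix_(idx, idx)]
        b, a = gls_oracle(spec.y, spec.X, K_obs, 0.4, 0.6,
                          K_full=spec.K, rec_idx=idx)
        np.testing.assert_allclose(sol.b_hat, b, atol=1e-8)
        np.testing.assert_allclose(sol.a_hat, a, atol=1e-8)

    def test_ssgblup_equals_pedigree_blup_when_g_is_a22(self, small_herd):
        """With G_adj = A22 the single-step correction cancels exactly."""
        ped, pheno = small_herd["ped"], small_herd["pheno"]
        A = s.build_a(ped)
        Ainv = s.build_a_inverse(ped, inbreeding=A.inbreeding)
        gmat = s.GMatrix(values=A.values.copy(), animal_ids=ped["animal"].values,
                         p_freqs=np.array([0.5]), scale=0.5)
        hinv = s.build_h_inverse(Ainv, A.values, gmat, np.arange(len(ped)),
                                 ped["animal"].values)
        spec_h = s.make_model_spec(pheno, "y", hinv.matrix, ped["animal"].values,
                                   sigma_a2=0.4, sigma_e2=0.6)
        spec_a = s.make_model_spec(pheno, "y", Ainv, ped["animal"].values,
                                   sigma_a2=0.4, sigma_e2=0.6)
        sol_h = s.solve_mme(spec_h, want_c22=False)
        sol_a = s.solve_mme(spec_a, want_c22=False)
        np.testing.assert_allclose(sol_h.a_hat, sol_a.a_hat, atol=1e-8)


class TestAiReml:
    def test_null_heritability_hits_boundary(self):
        rng = np.random.default_rng(1)
        n = 300
        y = rng.normal(size=n)
        spec = s.MixedModelSpec(y=y, X=np.ones((n, 1)),
                                record_animal_idx=np.arange(n), n_animals=n,
                                kinv=sp.eye(n).tocsr(), K=np.eye(n))
        # K = I is confounded with the residual; use a structured K instead
        cfg = SimConfig(n_founders=100, n_generations=2, n_chromosomes=1,
                        snps_per_chromosome=20, seed=2, h2_true=0.0,
                        sex_limited=False, n_qtl=5)
        ped = s.simulate_pedigree(cfg)
        geno = s.simulate_genotypes(ped, cfg)
        pheno, _ = s.simulate_phenotypes(ped, geno, cfg)
        spec = pedigree_mixed_model(ped, pheno)
        vc = s.ai_reml(spec)
        assert s.heritability(vc) < 0.08

    def test_balanced_half_sib_matches_anova(self):
        """On a balanced sire design REML equals the ANOVA estimator."""
        rng = np.random.default_rng(5)
        n_sire, n_prog = 25, 12
        sire_eff = rng.normal(0, 1.0, n_sire)
        y = np.repeat(sire_eff, n_prog) + rng.normal(0, np.sqrt(2.0),
                                                     n_sire * n_prog)
        spec = s.MixedModelSpec(
            y=y, X=np.ones((n_sire * n_prog, 1)),
            record_animal_idx=np.repeat(np.arange(n_sire), n_prog),
            n_animals=n_sire, kinv=sp.eye(n_sire).tocsr(), K=np.eye(n_sire))
        vc = s.ai_reml(spec)
        ybar_s = y.reshape(n_sire, n_prog).mean(axis=1)
        msb = n_prog * ((ybar_s - y.mean()) ** 2).sum() / (n_sire - 1)
        msw = ((y.reshape(n_sire, n_prog) - ybar_s[:, None]) ** 2).sum() \
            / (n_sire * (n_prog - 1))
        assert vc.sigma_a2 == pytest.approx((msb - msw) / n_prog, abs=1e-4)
        assert vc.sigma_e2 == pytest.approx(msw, abs=1e-4)

    def test_invariant_to_factor_relabeling(self, small_herd):
        ped, pheno = small_herd["ped"], small_herd["pheno"]
        vc1 = s.ai_reml(pedigree_mixed_model(ped, pheno))
        relabeled = pheno.copy()
        relabeled["cg"] = relabeled["cg"].max() + 1 - relabeled["cg"]
        vc2 = s.ai_reml(pedigree_mixed_model(ped, relabeled))
        np.testing.assert_allclose(vc1.params, vc2.params, atol=1e-6)

    def test_recovers_moderate_heritability(self):
        cfg = SimConfig(n_founders=300, n_generations=2, seed=7, h2_true=0.4,
                        sex_limited=False, prop_genotyped=1.0, n_qtl=100,
                        n_chromosomes=2, snps_per_chromosome=150)
        ped = s.simulate_pedigree(cfg)
        geno = s.simulate_genotypes(ped, cfg)
        pheno, _ = s.simulate_phenotypes(ped, geno, cfg)
        vc = s.ai_reml(pedigree_mixed_model(ped, pheno))
        assert s.heritability(vc) == pytest.approx(0.4, abs=0.12)


class TestBivariate:
    def test_near_duplicate_traits_give_unit_correlation(self):
        cfg = SimConfig(n_founders=200, n_generations=2, seed=9, n_qtl=150,
                        sex_limited=False, n_chromosomes=2,
                        snps_per_chromosome=100)
        ped = s.simulate_pedigree(cfg)
        geno = s.simulate_genotypes(ped, cfg)
        pheno, _, _ = s.simulate_phenotypes_bivariate(ped, geno, cfg,
                                                      h2_pair=(0.4, 0.4),
                                                      r_g=0.99)
        s1 = pedigree_mixed_model(ped, pheno, trait="y1")
        s2 = pedigree_mixed_model(ped, pheno, trait="y2")
        s2.K = s1.K
        vc = s.ai_reml_bivariate(s1, s2)
        assert s.genetic_correlation(vc) > 0.85

    def test_uncorrelated_traits(self):
        cfg = SimConfig(n_founders=300, n_generations=2, seed=10, n_qtl=200,
                        sex_limited=False, n_chromosomes=2,
                        snps_per_chromosome=100)
        ped = s.simulate_pedigree(cfg)
        geno = s.simulate_genotypes(ped, cfg)
        pheno, _, _ = s.simulate_phenotypes_bivariate(ped, geno, cfg,
                                                      h2_pair=(0.4, 0.4),
                                                      r_g=0.0)
        s1 = pedigree_mixed_model(ped, pheno, trait="y1")
        s2 = pedigree_mixed_model(ped, pheno, trait="y2")
        s2.K = s1.K
        vc = s.ai_reml_bivariate(s1, s2)
        assert abs(s.genetic_correlation(vc)) < 0.25
        assert abs(s.phenotypic_correlation(vc)) < 0.2


class TestMonteCarloSe:
    def _varcomp(self, sa=0.4, se=0.6, ai_inv=None):
        if ai_inv is None:
            ai_inv = np.zeros((2, 2))
        return s.VarComp(params=np.array([sa, se]),
                         names=["sigma_a2", "sigma_e2"], ai_inv=ai_inv,
                         converged=True, n_iter=1)

    def test_zero_information_gives_degenerate_interval(self):
        mc = s.mc_standard_errors(self._varcomp(), n_samples=500, seed=0)
        assert mc["h2"]["sd"] == pytest.approx(0.0)
        assert mc["h2"]["hpd_low"] == pytest.approx(0.4)
        assert mc["h2"]["hpd_high"] == pytest.approx(0.4)

    def test_matches_delta_method(self):
        ai_inv = np.array([[0.004, -0.001], [-0.001, 0.003]])
        vc = self._varcomp(ai_inv=ai_inv)
        mc = s.mc_standard_errors(vc, n_samples=50_000, seed=1)
        sa, se = 0.4, 0.6
        grad = np.array([se, -sa]) / (sa + se) ** 2
        delta_sd = np.sqrt(grad @ ai_inv @ grad)
        assert mc["h2"]["sd"] == pytest.approx(delta_sd, rel=0.2)

    def test_seed_reproducibility(self):
        ai_inv = np.array([[0.01, 0.0], [0.0, 0.01]])
        vc = self._varcomp(ai_inv=ai_inv)
        mc1 = s.mc_standard_errors(vc, n_samples=2000, seed=3)
        mc2 = s.mc_standard_errors(vc, n_samples=2000, seed=3)
        assert mc1["h2"] == mc2["h2"]

    def test_boundary_rejection_raises(self):
        vc = self._varcomp(sa=1e-6, se=1.0, ai_inv=np.diag([1.0, 0.001]))
        with pytest.raises(RuntimeError, match="boundary"):
            s.mc_standard_errors(vc, n_samples=2000, seed=0)


class TestHeritability:
    @pytest.mark.parametrize("sa, se, h2", [(1, 3, 0.25), (0, 1, 0.0),
                                            (2, 2, 0.5)])
    def test_arithmetic(self, sa, se, h2):
        vc = s.VarComp(params=np.array([sa, se], dtype=float),
                       names=["sigma_a2", "sigma_e2"],
                       ai_inv=np.zeros((2, 2)), converged=True, n_iter=1)
        assert s.heritability(vc) == pytest.approx(h2)

    def test_zero_total_variance(self):
        vc = s.VarComp(params=np.array([0.0, 0.0]),
                       names=["sigma_a2", "sigma_e2"],
                       ai_inv=np.zeros((2, 2)), converged=True, n_iter=1)
        with pytest.raises(ValueError):
            s.heritability(vc)
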