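"""Variance components by AI-REML, with Monte-Carlo standard errors.

Estimates h2 for a simulated trait with true h2 = 0.3 under the pedigree
animal model, then a bivariate model for two traits sharing QTL with a
genetic correlation of 0.7.
"""

import numpy as np
import scipy.sparse as sp

import ssgwas as s
from ssgwas.config import SimConfig

cfg = SimConfig(n_founders=500, n_generations=3, seed=5, prop_genotyped=1.0,
                n_qtl=200, h2_true=0.3)
ped = s.simulate_pedigree(cfg)
geno = s.simulate_genotypes(ped, cfg)
pheno, truth = s.simulate_phenotypes(ped, geno, cfg)

A = s.build_a(ped)
eye = sp.eye(len(ped)).tocsr()
spec = s.make_model_spec(pheno, "y", eye, ped["animal"].values, K=A.values)
vc = s.ai_reml(spec)
mc = s.mc_standard_errors(vc, seed=5)
print(f"sigma_a2 = {vc.sigma_a2:.3f}, sigma_e2 = {vc.sigma_e2:.3f} "
      f"({vc.n_iter} AI iterations)")
print(f"h2 = {s.heritability(vc):.3f} +/- {mc['h2']['sd']:.3f} "
      f"(true 0.30, 95% HPD [{mc['h2']['hpd_low']:.2f}, "
      f"{mc['h2']['hpd_high']:.2f}])")

pheno2, t1, t2 = s.simulate_phenotypes_bivariate(ped, geno, cfg,
                                                 h2_pair=(0.3, 0.3), r_g=0.7)
s1 = s.make_model_spec(pheno2, "y1", eye, ped["animal"].values, K=A.values)
s2 = s.make_model_spec(pheno2, "y2", eye, ped["animal"].values, K=A.values)
vc2 = s.ai_reml_bivariate(s1, s2)
mc2 = s.mc_standard_errors(vc2, seed=6)
rg = mc2["r_g"]
print(f"genetic correlation = {rg['estimate']:.3f} +/- {rg['sd']:.3f} "
      f"(true 0.70, significant: {rg['significant']})")
print(f"phenotypic correlation = {mc2['r_p']['estimate']:.3f}")
# A correlation is declared significant when its 95% HPD excludes zero.
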