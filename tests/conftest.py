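import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ssgwas as s
from ssgwas.config import SimConfig


def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return pd.DataFrame({
        "animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
        "sex": ["M", "F", "M"], "generation": [0, 0, 1],
        "birth_month": [1, 2, 3], "dam_parity": [1, 1, 1],
    })


@pytest.fixture
def trio():
    return trio_pedigree()


@pytest.fixture(scope="session")
def small_herd():
    """A fully genotyped two-generation herd used across modules."""
    cfg = SimConfig(n_founders=80, n_generations=2, n_chromosomes=2,
                    snps_per_chromosome=100, seed=11, prop_genotyped=1.0,
                    sex_limited=False, n_qtl=30, h2_true=0.4)
    ped = s.simulate_pedigree(cfg)
    geno = s.simulate_genotypes(ped, cfg)
    pheno, truth = s.simulate_phenotypes(ped, geno, cfg)
    return {"cfg": cfg, "ped": ped, "geno": geno, "pheno": pheno, "truth": truth}


def make_geno(calls, chrom=None, pos=None):
    """GenotypeData from a raw 0/1/2/-1 matrix, for hand-crafted QC tests."""
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    snp_map = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
        "pos_bp": pos if pos is not None else (np.arange(m) + 1) * 1000,
    })
    return s.GenotypeData(calls=calls, animal_ids=np.arange(1, n + 1),
                          snp_map=snp_map)


def pedigree_mixed_model(ped, pheno, trait="y", **kw):
    """MixedModelSpec with the pedigree relationship matrix as K."""
    A = s.build_a(ped)
    spec = s.make_model_spec(pheno, trait, sp.eye(len(ped)).tocsr(),
                             ped["animal"].values, K=A.values, **kw)
    return spec
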