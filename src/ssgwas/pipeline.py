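"""End-to-end driver: simulate -> QC -> kinship -> REML -> GWAS.

Each stage writes fixed-precision TSVs into the output directory together
with a manifest (seed, configuration hash, stage list), so re-running the
same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from . import io as io_mod
from . import kinship, mme, qc, reml
from .config import PipelineConfig
from .simulate import (GenotypeData, simulate_genotypes, simulate_pedigree,
                       simulate_phenotypes)

log = logging.getLogger(__name__)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages in order and return the in-memory results.

    Stage failures propagate with the stage name attached. Outputs land in
    ``outdir`` (created if needed); the manifest records seed and config
    hash in every run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config_hash(config), "seed": config.seed}
    stage = None
    try:
        for stage in config.stages:
            _STAGES[stage](config, outdir, results)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest = {
        "seed": config.seed,
        "config_hash": results["config_hash"],
        "stages": list(config.stages),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def _stage_simulate(config, outdir, results):
    cfg = config.sim
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    pheno, truth = simulate_phenotypes(ped, geno, cfg)
    io_mod.write_pedigree(ped, outdir / "pedigree.csv")
    io_mod.write_phenotypes(pheno, outdir / "phenotypes.csv")
    io_mod.write_dense_genotypes(geno, outdir / "genotypes")
    io_mod.write_truth(truth, outdir / "truth.tsv")
    results.update(ped=ped, geno=geno, pheno=pheno, truth=truth)


def _stage_qc(config, outdir, results):
    thr = config.qc
    thr.validate()
    geno = results["geno"]
    geno, rm_maf_pre = qc.filter_maf(geno, thr.maf_pre)
    geno, _ = qc.detect_mendelian_conflicts(geno, results["ped"])
    geno, rm_maf = qc.filter_maf(geno, thr.maf_post)
    geno, rm_hwe = qc.filter_hwe(geno, thr.hwe_het_dev)
    geno, cr_report = qc.filter_callrate(geno, thr.callrate_snp_post,
                                         thr.callrate_animal)
    per_snp, per_chrom = qc.compute_maf_summary(geno)
    per_chrom.to_csv(outdir / "maf_by_chromosome.tsv", sep="\t", index=False,
                     float_format="%.6f")
    report = cr_report.to_frame()
    report.loc[len(report)] = ["maf_pre", "snp", len(rm_maf_pre)]
    report.loc[len(report)] = ["maf_post", "snp", len(rm_maf)]
    report.loc[len(report)] = ["hwe", "snp", len(rm_hwe)]
    report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    results["geno_qc"] = geno


def _stage_kinship(config, outdir, results):
    ped = results["ped"]
    geno = results.get("geno_qc", results["geno"])
    prop = config.sim.prop_genotyped
    rng = np.random.default_rng(config.seed + 10)
    n = geno.n_animals
    g_rows = np.sort(rng.choice(n, size=max(2, int(round(prop * n))), replace=False))
    geno_sub = geno.subset(animal_idx=g_rows)
    id_to_row = {a: i for i, a in enumerate(ped["animal"].values)}
    g_rows = np.array([id_to_row[a] for a in geno_sub.animal_ids])

    A = kinship.build_a(ped)
    Ainv = kinship.build_a_inverse(ped, inbreeding=A.inbreeding)
    A22 = A.values[np.ix_(g_rows, g_rows)]
    g0 = kinship.build_g(geno_sub)
    g_blend = kinship.blend_g(g0, config.blend_lambda, config.blend_beta)
    if config.tune_mode == "mean-matching":
        g_adj, delta = kinship.tune_g_to_a22(g_blend, A22)
    else:
        g_adj, delta = g_blend, 1.0
    hinv = kinship.build_h_inverse(Ainv, A22, g_adj, g_rows, ped["animal"].values)
    results.update(A=A, Ainv=Ainv, A22=A22, G=g_adj, delta=delta, hinv=hinv,
                   geno_sub=geno_sub, genotyped_rows=g_rows)


def _stage_reml(config, outdir, results):
    ped = results["ped"]
    hinv = results["hinv"]
    spec = mme.make_model_spec(results["pheno"], "y", hinv.matrix,
                               ped["animal"].values,
                               genotyped_ids=results["geno_sub"].animal_ids)
    vc = reml.ai_reml(spec)
    h2 = reml.heritability(vc)
    mc = reml.mc_standard_errors(vc, n_samples=5000, seed=config.seed + 20)
    pd.DataFrame([{**vc.as_dict(), "h2": h2,
                   "h2_sd": mc["h2"]["sd"]}]).to_csv(
        outdir / "variance_components.tsv", sep="\t", index=False,
        float_format="%.6f")
    results.update(varcomp=vc, h2=h2, spec=spec)


def _stage_gwas(config, outdir, results):
    spec = results["spec"]
    vc = results["varcomp"]
    spec.sigma_a2, spec.sigma_e2 = vc.sigma_a2, vc.sigma_e2
    sol = mme.solve_mme(spec)
    G = results["G"]
    geno_sub = results["geno_sub"]
    M = kinship.centered_m(geno_sub)
    g_hat = gwas_mod.backsolve_snp_effects(M, G.scale, G.values, sol.a22_hat,
                                           lam=G.lam, delta=G.delta)
    sd_g = gwas_mod.snp_effect_pev(M, G.scale, G.values, sol.C22, vc.sigma_a2,
                                   lam=G.lam, delta=G.delta)
    p = gwas_mod.snp_pvalues(g_hat, sd_g)
    m_eff = gwas_mod.effective_tests(geno_sub)
    thr = gwas_mod.thresholds(m_eff, alpha=config.alpha)
    res = geno_sub.snp_map.assign(
        g_hat=g_hat, sd_g=sd_g, p=p,
        variance_explained_pct=gwas_mod.variance_explained(
            g_hat, G.p_freqs, vc.sigma_a2))
    manhattan, qq, hits = gwas_mod.gwas_tables(res, thr)
    manhattan.to_csv(outdir / "gwas_results.tsv", sep="\t", index=False,
                     float_format="%.6g")
    qq.to_csv(outdir / "gwas_qq.tsv", sep="\t", index=False, float_format="%.6f")
    hits.to_csv(outdir / "gwas_hits.tsv", sep="\t", index=False,
                float_format="%.6g")
    (outdir / "thresholds.json").write_text(json.dumps({
        "m_eff": thr.m_eff, "alpha": thr.alpha,
        "significant_logp": thr.significant_logp,
        "suggestive_p": thr.suggestive_p,
        "inflation": gwas_mod.inflation_factor(p[~np.isnan(p)]),
    }, indent=2, sort_keys=True))
    results.update(gwas=manhattan, thresholds=thr, hits=hits)


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "kinship": _stage_kinship,
    "reml": _stage_reml,
    "gwas": _stage_gwas,
}
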