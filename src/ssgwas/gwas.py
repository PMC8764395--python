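"""SNP allele-substitution effects back-solved from single-step breeding values.

Given the estimated breeding values of the genotyped animals (a22_hat) and
the genomic relationship machinery, the per-SNP allele substitution effect is

    g_hat = lambda * delta * [1 / (2 sum p q)] * M' G^-1 a22_hat

with prediction-error variance

    Var(g_hat) = (lambda delta / (2 sum pq))^2 *
                 diag( M' G^-1 (G sigma_a2 - C22) G^-1 M )

and two-sided normal p-values 2 (1 - Phi(|g_hat| / sd(g_hat))). Multiple
testing is handled with an effective number of independent tests derived
from the eigenvalues of the SNP correlation matrix, and the scan is
sanity-checked with the median-chi-square genomic inflation factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeData

log = logging.getLogger(__name__)

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))   # 0.454936...


@dataclass
class GwasThresholds:
    m_eff: float
    alpha: float
    significant_p: float
    significant_logp: float
    suggestive_p: float


def backsolve_snp_effects(M: np.ndarray, scale: float, G: np.ndarray,
                          a22_hat: np.ndarray, lam: float = 1.0,
                          delta: float = 1.0) -> np.ndarray:
    """g_hat = lam * delta * (1/scale) * M' G^-1 a22_hat.

    ``M`` is the genotype matrix centered by twice the allele frequencies
    (animals x SNPs) and ``scale`` its associated 2*sum(pq).
    """
    if M.shape[0] != len(a22_hat) or M.shape[0] != G.shape[0]:
        raise ValueError("M, G and a22_hat must agree on the genotyped animals")
    try:
        Ginv_a = np.linalg.solve(G, a22_hat)
    except np.linalg.LinAlgError as exc:
        raise ValueError("G is singular; blend before back-solving") from exc
    return lam * delta * (M.T @ Ginv_a) / scale


def snp_effect_pev(M: np.ndarray, scale: float, G: np.ndarray,
                   C22: np.ndarray, sigma_a2: float, lam: float = 1.0,
                   delta: float = 1.0) -> np.ndarray:
    """Standard errors of the back-solved SNP effects.

    ``C22`` is the genotyped block of the inverse MME coefficient matrix on
    the sigma_e2 scale, so that Var(a22_hat) = G sigma_a2 - C22. Small
    negative diagonal values (numerical) are clipped to zero; larger ones
    indicate a scale mismatch and raise.
    """
    var_a22 = G * sigma_a2 - C22
    B = np.linalg.solve(G, M)                 # G^-1 M
    S = var_a22 @ B
    diag = np.einsum("ij,ij->j", B, S)
    c = lam * delta / scale
    var_g = (c * c) * diag
    tol = 1e-10 * max(1.0, np.abs(var_g).max())
    if (var_g < -tol).any():
        raise ValueError("negative PEV diagonal: C22 scale mismatch with G sigma_a2")
    n_clip = int((var_g < 0).sum())
    if n_clip:
        log.info("clipped %d tiny negative PEV values to 0", n_clip)
    return np.sqrt(np.clip(var_g, 0.0, None))


def snp_pvalues(g_hat: np.ndarray, sd_g: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values; SNPs with sd 0 are reported as NaN."""
    g_hat = np.asarray(g_hat, dtype=float)
    sd_g = np.asarray(sd_g, dtype=float)
    p = np.full(len(g_hat), np.nan)
    ok = sd_g > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("%d SNPs with zero PEV variance excluded from testing", n_excluded)
    z = np.abs(g_hat[ok] / sd_g[ok])
    p[ok] = 2.0 * stats.norm.sf(z)
    return p


def variance_explained(g_hat: np.ndarray, p_freqs: np.ndarray,
                       sigma_a2: float) -> np.ndarray:
    """Percent of additive variance per SNP: 100 * 2 p q g^2 / sigma_a2."""
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    pq = p_freqs * (1.0 - p_freqs)
    return 100.0 * 2.0 * pq * np.asarray(g_hat) ** 2 / sigma_a2


def _meff_from_eigvals(eigvals: np.ndarray) -> float:
    """Effective tests from eigenvalues: sum of the integral indicator and
    the fractional part, f(x) = 1(x >= 1) + (x - floor(x))."""
    lam = np.clip(eigvals, 0.0, None)
    # snap near-integer eigenvalues so the fractional part is stable
    near = np.round(lam)
    lam = np.where(np.abs(lam - near) < 1e-9, near, lam)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def effective_tests(geno_or_corr: Union[GenotypeData, np.ndarray],
                    method: str = "li-ji",
                    block_size: Optional[int] = None) -> float:
    """Effective number of independent tests (eigenvalue decomposition).

    For a GenotypeData input the SNP correlation matrix is formed per
    chromosome (optionally in fixed-size blocks for memory) and the
    per-block effective counts are summed. Zero-variance SNPs are skipped.
    """
    if method != "li-ji":
        raise ValueError(f"unknown method {method!r}")

    def block_meff(corr: np.ndarray) -> float:
        vals = np.linalg.eigvalsh(corr)
        if (vals < -1e-8).any():
            log.info("clipped negative eigenvalues of a non-PSD correlation block")
        return _meff_from_eigvals(vals)

    if isinstance(geno_or_corr, np.ndarray):
        return block_meff(np.asarray(geno_or_corr, dtype=float))

    geno = geno_or_corr
    d = geno.dosages()
    total = 0.0
    for chrom, grp in geno.snp_map.groupby("chrom"):
        idx = grp.index.values
        cols = d[:, idx]
        sd = np.nanstd(cols, axis=0)
        cols = cols[:, sd > 0]
        if cols.shape[1] == 0:
            continue
        starts = range(0, cols.shape[1], block_size) if block_size else [0]
        stop = block_size if block_size else cols.shape[1]
        for s in starts:
            sub = cols[:, s:s + stop]
            if sub.shape[1] == 1:
                total += 1.0
                continue
            if np.isnan(sub).any():
                corr = pd.DataFrame(sub).corr().values
            else:
                corr = np.corrcoef(sub, rowvar=False)
            total += block_meff(corr)
    return total


def thresholds(m_eff: float, alpha: float = 0.05,
               suggestive_mode: str = "one-false-positive") -> GwasThresholds:
    """Genome-wide and suggestive significance levels for ``m_eff`` tests.

    The genome-wide level is the Bonferroni-style alpha / m_eff; the
    suggestive level defaults to 1 / m_eff (one expected false positive per
    genome scan), with ``suggestive_mode='alpha10'`` giving 0.1 / m_eff.
    """
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    sig_p = alpha / m_eff
    if suggestive_mode == "one-false-positive":
        sug_p = 1.0 / m_eff
    elif suggestive_mode == "alpha10":
        sug_p = 0.1 / m_eff
    else:
        raise ValueError(f"unknown suggestive_mode {suggestive_mode!r}")
    return GwasThresholds(m_eff=float(m_eff), alpha=alpha,
                          significant_p=sig_p,
                          significant_logp=-np.log10(sig_p),
                          suggestive_p=sug_p)


def inflation_factor(p_values: np.ndarray) -> float:
    """Genomic inflation: median association chi-square over the 1-df null
    median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if len(p) < 100:
        warnings.warn("fewer than 100 p-values: inflation factor is unstable")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def gwas_tables(results: pd.DataFrame, thr: GwasThresholds
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Manhattan table (with significance class), QQ table and hit list.

    ``results`` needs columns snp_id, chrom, pos_bp, p. Boundary hits
    (p exactly at a threshold) count as the stronger class.
    """
    res = results.copy()
    res["minus_log10_p"] = -np.log10(res["p"])
    cls = np.where(res["p"] <= thr.significant_p, "significant",
                   np.where(res["p"] <= thr.suggestive_p, "suggestive", "none"))
    cls = np.where(res["p"].isna(), "untested", cls)
    res["class"] = cls

    tested = res.dropna(subset=["p"]).sort_values("p").reset_index(drop=True)
    m = len(tested)
    qq = pd.DataFrame({
        "expected_logp": -np.log10((np.arange(1, m + 1) - 0.5) / m),
        "observed_logp": tested["minus_log10_p"].values,
    })
    hits = tested[tested["class"].isin(["significant", "suggestive"])].reset_index(drop=True)
    return res, qq, hits
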