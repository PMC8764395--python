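"""Post-GWAS interpretation: SNP-to-gene mapping, gene-set enrichment,
candidate-region/QTL-interval overlap and localized LD around top hits.

SNPs with nominal p < 0.01 define the hit gene set; all genes with at
least one mapped SNP define the background. Enrichment uses the one-sided
hypergeometric tail with Benjamini-Hochberg FDR across terms, plus the
minimum-overlap (3 genes) and minimum-percentage (4% of the term) filters.
All coordinates are 1-based inclusive; overlap requires >= 1 shared bp.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeData

log = logging.getLogger(__name__)

LD_CLASS_EDGES = [0.2, 0.4, 0.6, 0.8]
LD_CLASS_NAMES = ["blue", "light_blue", "green", "yellow", "red"]


def _gene_gap(pos: int, start: int, end: int) -> int:
    """bp gap between a SNP and a gene interval; 0 when inside."""
    if start <= pos <= end:
        return 0
    return min(abs(pos - start), abs(pos - end))


def map_snps_to_genes(snps: pd.DataFrame, annotation: pd.DataFrame,
                      window_bp: int = 15_000) -> pd.DataFrame:
    """Map each SNP to every gene within ``window_bp`` of its interval.

    ``snps`` needs snp_id, chrom, pos_bp; ``annotation`` needs gene_id,
    chrom, start_bp, end_bp. The nearest gene(s) per SNP are flagged, with
    ties all reported. SNPs on chromosomes absent from the annotation are
    skipped (logged).
    """
    bad = (annotation["start_bp"] > annotation["end_bp"]).sum()
    if bad:
        raise ValueError(f"{bad} annotation rows with start > end")
    rows = []
    ann_by_chrom = dict(tuple(annotation.groupby("chrom")))
    n_skipped = 0
    for _, s in snps.iterrows():
        genes = ann_by_chrom.get(s["chrom"])
        if genes is None:
            n_skipped += 1
            continue
        gaps = np.array([_gene_gap(s["pos_bp"], a, b)
                         for a, b in zip(genes["start_bp"], genes["end_bp"])])
        sel = gaps <= window_bp
        if not sel.any():
            continue
        nearest = gaps[sel].min()
        for g, gap in zip(genes["gene_id"].values[sel], gaps[sel]):
            rows.append((s["snp_id"], g, int(gap), gap == 0, gap == nearest))
    if n_skipped:
        log.info("skipped %d SNPs on chromosomes absent from the annotation", n_skipped)
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "distance_bp",
                                       "within", "nearest"])


def select_gene_hits(gwas_results: pd.DataFrame, annotation: pd.DataFrame,
                     p_nominal: float = 0.01, window_bp: int = 15_000
                     ) -> tuple[set, set]:
    """Hit genes (>= 1 SNP below ``p_nominal``) and the mapped background.

    The background is every gene with at least one SNP within the mapping
    window, each gene counted once.
    """
    mapping = map_snps_to_genes(
        gwas_results[["snp_id", "chrom", "pos_bp"]], annotation, window_bp)
    if mapping.empty:
        raise ValueError("no SNP maps to any gene: empty background")
    background = set(mapping["gene_id"])
    sub = gwas_results.loc[gwas_results["p"] < p_nominal, "snp_id"]
    hits = set(mapping.loc[mapping["snp_id"].isin(set(sub)), "gene_id"])
    return hits, background


def bh_adjust(p_list: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_list), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(hit_genes: set, background_genes: set,
           terms: Mapping[str, Iterable], fdr: float = 0.05,
           min_genes: int = 3, min_pct: float = 4.0) -> pd.DataFrame:
    """Hypergeometric term enrichment of the hit set against the background.

    Per term: one-sided tail P(X >= overlap) for X ~ Hypergeom(N = background,
    K = term genes in background, n = hits). A term passes when
    bh_fdr < ``fdr``, overlap >= ``min_genes`` and the overlap covers at
    least ``min_pct`` percent of the term's background genes. Terms with no
    background intersection are skipped.
    """
    if not set(hit_genes) <= set(background_genes):
        raise ValueError("hit genes must be a subset of the background")
    N = len(background_genes)
    n = len(hit_genes)
    rows = []
    for term_id, members in terms.items():
        in_bg = set(members) & set(background_genes)
        if not in_bg:
            log.info("term %s has no background genes; skipped", term_id)
            continue
        K = len(in_bg)
        overlap = in_bg & set(hit_genes)
        k = len(overlap)
        raw_p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": term_id,
            "n_background_in_term": K,
            "n_hits_in_term": k,
            "pct_of_term": 100.0 * k / K,
            "raw_p": raw_p,
            "overlap_genes": ",".join(sorted(map(str, overlap))),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["bh_fdr"] = bh_adjust(out["raw_p"])
    out["passes_filters"] = ((out["bh_fdr"] < fdr)
                             & (out["n_hits_in_term"] >= min_genes)
                             & (out["pct_of_term"] >= min_pct))
    return out.sort_values("raw_p").reset_index(drop=True)


def region_qtl_overlap(candidate_snps: pd.DataFrame, qtl_intervals: pd.DataFrame,
                       flank_bp: int = 500_000
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap of SNP +/- ``flank_bp`` candidate regions with QTL intervals.

    ``qtl_intervals`` needs chrom, start_bp, end_bp, category. Malformed
    rows (start > end or missing fields) are skipped with a log message.
    Returns the per-overlap table and the percentage share per category.
    """
    qtl = qtl_intervals.copy()
    ok = (qtl[["chrom", "start_bp", "end_bp", "category"]].notna().all(axis=1)
          & (qtl["start_bp"] <= qtl["end_bp"]))
    if (~ok).any():
        log.info("skipped %d malformed QTL rows", int((~ok).sum()))
    qtl = qtl[ok]
    rows = []
    for _, s in candidate_snps.iterrows():
        lo, hi = s["pos_bp"] - flank_bp, s["pos_bp"] + flank_bp
        sub = qtl[(qtl["chrom"] == s["chrom"])
                  & (qtl["end_bp"] >= lo) & (qtl["start_bp"] <= hi)]
        for _, q in sub.iterrows():
            rows.append((s["snp_id"], s["chrom"], q["start_bp"], q["end_bp"],
                         q["category"]))
    overlaps = pd.DataFrame(rows, columns=["snp_id", "chrom", "qtl_start_bp",
                                           "qtl_end_bp", "category"])
    if overlaps.empty:
        return overlaps, pd.DataFrame(columns=["category", "n", "pct"])
    counts = overlaps["category"].value_counts()
    pct = pd.DataFrame({"category": counts.index, "n": counts.values,
                        "pct": 100.0 * counts.values / counts.sum()})
    return overlaps, pct.reset_index(drop=True)


def ld_class(r2: float) -> str:
    """Five-bin LD class; boundary values go to the lower class."""
    return LD_CLASS_NAMES[int(np.digitize(r2, LD_CLASS_EDGES, right=True))]


def localized_ld(geno: GenotypeData, focal_snp: str,
                 window_bp: int = 500_000) -> pd.DataFrame:
    """r^2 of every SNP within +/- ``window_bp`` of the focal SNP.

    Zero-variance SNPs are skipped; the focal SNP itself appears with
    r^2 = 1 (class red).
    """
    smap = geno.snp_map
    sel = smap["snp_id"] == focal_snp
    if not sel.any():
        raise ValueError(f"focal SNP {focal_snp!r} not found")
    focal = smap[sel].iloc[0]
    idx_focal = int(smap.index[sel][0])
    d = geno.dosages()
    x = d[:, idx_focal]
    if np.nanstd(x) == 0:
        raise ValueError("focal SNP has zero variance")
    in_window = smap[(smap["chrom"] == focal["chrom"])
                     & (smap["pos_bp"] >= focal["pos_bp"] - window_bp)
                     & (smap["pos_bp"] <= focal["pos_bp"] + window_bp)]
    rows = []
    for j, s in in_window.iterrows():
        yv = d[:, j]
        ok = ~(np.isnan(x) | np.isnan(yv))
        if ok.sum() < 3 or yv[ok].std() == 0 or x[ok].std() == 0:
            continue
        r2 = float(np.corrcoef(x[ok], yv[ok])[0, 1] ** 2)
        rows.append((s["snp_id"], int(s["pos_bp"]),
                     int(s["pos_bp"] - focal["pos_bp"]), r2, ld_class(r2)))
    return pd.DataFrame(rows, columns=["snp_id", "pos_bp", "dist_bp", "r2",
                                       "ld_class"])
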