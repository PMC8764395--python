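"""Genotype and growth-record quality control.

Marker filters (MAF, call rate, Hardy-Weinberg heterozygosity deviation),
pedigree-genotype conflict detection, minor-allele-frequency summaries,
principal components of a relationship matrix, the masking cross-validation
harness for imputation accuracy, and the weight-on-age regression that
derives average daily gain (ADG).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeData

log = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Per-filter removal counts; removed + surviving = input, per axis."""

    steps: list = field(default_factory=list)   # (name, axis, removed_ids)
    n_snps_in: int = 0
    n_animals_in: int = 0
    n_snps_out: int = 0
    n_animals_out: int = 0

    def add(self, name: str, axis: str, removed_ids) -> None:
        self.steps.append((name, axis, list(removed_ids)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, a, len(ids)) for n, a, ids in self.steps],
            columns=["filter", "axis", "n_removed"],
        )


def filter_maf(geno: GenotypeData, threshold: float) -> tuple[GenotypeData, np.ndarray]:
    """Remove SNPs with minor allele frequency below ``threshold``.

    MAF is computed on non-missing calls; an all-missing SNP has MAF 0 and
    is removed with a warning.
    """
    maf = geno.maf()
    all_missing = np.isnan(maf)
    if all_missing.any():
        warnings.warn(f"{all_missing.sum()} all-missing SNPs treated as MAF 0 and removed")
    maf = np.where(all_missing, 0.0, maf)
    keep = maf >= threshold
    removed = geno.snp_map["snp_id"].values[~keep]
    return geno.subset(snp_idx=np.flatnonzero(keep)), removed


def filter_hwe(geno: GenotypeData, dev_threshold: float = 0.15
               ) -> tuple[GenotypeData, np.ndarray]:
    """Remove SNPs whose observed heterozygote proportion deviates from the
    Hardy-Weinberg expectation 2p(1-p) by more than ``dev_threshold``.

    Proportions are computed over non-missing calls.
    """
    d = geno.dosages()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
        obs_het = np.nanmean(d == 1, axis=0)
    exp_het = 2.0 * p * (1.0 - p)
    dev = np.abs(obs_het - exp_het)
    dev = np.where(np.isnan(dev), np.inf, dev)
    keep = dev <= dev_threshold
    removed = geno.snp_map["snp_id"].values[~keep]
    return geno.subset(snp_idx=np.flatnonzero(keep)), removed


def filter_callrate(geno: GenotypeData, snp_thr: float = 0.90,
                    animal_thr: float = 0.95) -> tuple[GenotypeData, QcReport]:
    """SNP call-rate filter first, then animal call rate on surviving SNPs."""
    report = QcReport(n_snps_in=geno.n_snps, n_animals_in=geno.n_animals)
    keep_snp = geno.call_rate_snp() >= snp_thr
    report.add("callrate_snp", "snp", geno.snp_map["snp_id"].values[~keep_snp])
    geno = geno.subset(snp_idx=np.flatnonzero(keep_snp))
    keep_animal = geno.call_rate_animal() >= animal_thr
    report.add("callrate_animal", "animal", geno.animal_ids[~keep_animal])
    geno = geno.subset(animal_idx=np.flatnonzero(keep_animal))
    if geno.n_snps == 0 or geno.n_animals == 0:
        raise ValueError("call-rate filtering removed all SNPs or all animals")
    report.n_snps_out, report.n_animals_out = geno.n_snps, geno.n_animals
    return geno, report


def detect_mendelian_conflicts(geno: GenotypeData, ped: pd.DataFrame,
                               resolve: bool = True
                               ) -> tuple[GenotypeData, pd.DataFrame]:
    """Opposite-homozygote conflicts between parent and offspring.

    A conflict is a parent homozygous 0 with offspring homozygous 2 (or the
    reverse) at a SNP; with two homozygous-same parents, a heterozygous
    offspring is also impossible. Resolution blanks the offspring call (the
    less-replicated observation).
    """
    id_to_row = {a: i for i, a in enumerate(geno.animal_ids)}
    out = geno.copy() if resolve else geno
    rows = []
    for _, rec in ped.iterrows():
        off = rec["animal"]
        if off not in id_to_row:
            continue
        o = id_to_row[off]
        parents = [p for p in (rec["sire"], rec["dam"]) if p in id_to_row and p != 0]
        conflict = np.zeros(geno.n_snps, dtype=bool)
        for p in parents:
            pc = geno.calls[id_to_row[p]]
            oc = geno.calls[o]
            conflict |= (pc == 0) & (oc == 2)
            conflict |= (pc == 2) & (oc == 0)
        if len(parents) == 2:
            s, d = (geno.calls[id_to_row[p]] for p in parents)
            oc = geno.calls[o]
            conflict |= (s == 0) & (d == 0) & (oc == 1)
            conflict |= (s == 2) & (d == 2) & (oc == 1)
        n = int(conflict.sum())
        if n:
            rows.append((off, n))
            if resolve:
                out.calls[o, conflict] = MISSING
    table = pd.DataFrame(rows, columns=["animal", "n_conflicts"])
    return out, table


def compute_maf_summary(geno: GenotypeData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP MAF plus per-chromosome mean and SD."""
    maf = geno.maf()
    per_snp = geno.snp_map.assign(maf=maf)
    per_chrom = (per_snp.groupby("chrom")["maf"]
                 .agg(["mean", "std", "count"]).reset_index()
                 .rename(columns={"mean": "maf_mean", "std": "maf_sd", "count": "n_snps"}))
    return per_snp, per_chrom


def _pairwise_r2(d: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """r^2 between dosage columns, complete cases per pair."""
    out = np.empty(len(i_idx))
    complete = ~np.isnan(d).any(axis=0)
    # fast path: correlation matrix when all columns complete
    for k, (i, j) in enumerate(zip(i_idx, j_idx)):
        x, y = d[:, i], d[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            out[k] = np.nan
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[k] = r * r
    return out


def compute_ld(geno: GenotypeData, max_pairs_per_chrom: int = 200_000,
               seed: Optional[int] = None) -> pd.DataFrame:
    """Within-chromosome LD: squared Pearson correlation of allele counts.

    All within-chromosome pairs are enumerated; when a chromosome exceeds
    ``max_pairs_per_chrom`` pairs, a seeded subsample is used. Zero-variance
    SNPs in a pair yield NaN and are dropped from the output.
    """
    rng = np.random.default_rng(seed)
    d = geno.dosages()
    frames = []
    for chrom, grp in geno.snp_map.groupby("chrom"):
        idx = grp.index.values
        m = len(idx)
        if m < 2:
            continue
        iu, ju = np.triu_indices(m, k=1)
        if len(iu) > max_pairs_per_chrom:
            sel = rng.choice(len(iu), size=max_pairs_per_chrom, replace=False)
            iu, ju = iu[sel], ju[sel]
        cols = d[:, idx]
        if not np.isnan(cols).any():
            with np.errstate(invalid="ignore"):
                cmat = np.corrcoef(cols, rowvar=False)
            r2 = cmat[iu, ju] ** 2
        else:
            r2 = _pairwise_r2(cols, iu, ju)
        pos = grp["pos_bp"].values
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "snp_i": grp["snp_id"].values[iu],
            "snp_j": grp["snp_id"].values[ju],
            "dist_bp": np.abs(pos[ju] - pos[iu]),
            "r2": r2,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "snp_i", "snp_j", "dist_bp", "r2"])
    out = pd.concat(frames, ignore_index=True)
    n_bad = out["r2"].isna().sum()
    if n_bad:
        log.info("dropped %d LD pairs with zero-variance SNPs", n_bad)
    return out.dropna(subset=["r2"]).reset_index(drop=True)


def ld_decay_summary(ld: pd.DataFrame, bin_bp: int = 1_000_000) -> pd.DataFrame:
    """Mean r^2 in distance bins of ``bin_bp``."""
    b = (ld["dist_bp"] // bin_bp).astype(int)
    out = (ld.assign(bin=b).groupby("bin")["r2"]
           .agg(["mean", "std", "count"]).reset_index())
    out["dist_mb_low"] = out["bin"] * bin_bp / 1e6
    return out.rename(columns={"mean": "r2_mean", "std": "r2_sd", "count": "n_pairs"})


def pca_of_g(G: np.ndarray, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a (symmetric) relationship matrix.

    Returns eigenvalues in decreasing order and the first-``k`` principal
    coordinates (eigenvector scaled by sqrt eigenvalue).
    """
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("relationship matrix must be symmetric")
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(k, len(vals))
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    return vals, coords


def mean_imputer(masked: GenotypeData, ped=None) -> np.ndarray:
    """Per-SNP mean dosage (2p over observed calls)."""
    d = masked.dosages()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    out = d.copy()
    miss = np.isnan(out)
    out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
    return out


def parent_average_imputer(masked: GenotypeData, ped: pd.DataFrame) -> np.ndarray:
    """Parental-average dosage when a genotyped parent is observed at the SNP,
    else the per-SNP mean."""
    out = mean_imputer(masked)
    d = masked.dosages()
    id_to_row = {a: i for i, a in enumerate(masked.animal_ids)}
    parents = {r["animal"]: (r["sire"], r["dam"]) for _, r in ped.iterrows()}
    for a, row in id_to_row.items():
        miss = np.isnan(d[row])
        if not miss.any() or a not in parents:
            continue
        vals = []
        for p in parents[a]:
            if p != 0 and p in id_to_row:
                vals.append(d[id_to_row[p]])
        if not vals:
            continue
        pstack = np.vstack(vals)
        with np.errstate(invalid="ignore"):
            pavg = np.nanmean(pstack, axis=0)
        use = miss & ~np.isnan(pavg)
        out[row, use] = pavg[use]
    return out


def imputation_cv(geno_full: GenotypeData, overlap_snp_idx: np.ndarray,
                  n_rounds: int = 10, n_animals_per_round: int = 10,
                  imputer: Optional[Callable] = None, ped: Optional[pd.DataFrame] = None,
                  seed: int = 0) -> pd.DataFrame:
    """Masking cross-validation of imputation accuracy.

    Each round hides the overlap SNPs in ``n_animals_per_round`` animals,
    imputes them with ``imputer`` (default: parental average falling back to
    per-SNP mean), and reports the Pearson correlation between true and
    imputed dosages on the masked cells.
    """
    if imputer is None:
        imputer = parent_average_imputer if ped is not None else mean_imputer
    rng = np.random.default_rng(seed)
    overlap_snp_idx = np.asarray(overlap_snp_idx)
    truth = geno_full.dosages()
    if np.isnan(truth[:, overlap_snp_idx]).any():
        raise ValueError("genotypes must be complete at the masked positions")
    rows = []
    for rnd in range(n_rounds):
        animals = rng.choice(geno_full.n_animals, size=n_animals_per_round, replace=False)
        masked = geno_full.copy()
        masked.calls[np.ix_(animals, overlap_snp_idx)] = MISSING
        imputed = imputer(masked, ped)
        t = truth[np.ix_(animals, overlap_snp_idx)].ravel()
        m = imputed[np.ix_(animals, overlap_snp_idx)].ravel()
        ok = ~np.isnan(m)
        n_fail = int((~ok).sum())
        if n_fail:
            log.warning("round %d: %d cells left missing by the imputer", rnd, n_fail)
        if t[ok].std() == 0 or m[ok].std() == 0:
            acc = 0.0
        else:
            acc = float(np.corrcoef(t[ok], m[ok])[0, 1])
        rows.append((rnd, acc, int(ok.sum())))
    return pd.DataFrame(rows, columns=["round", "accuracy", "n_cells"])


def derive_adg(weights: pd.DataFrame, r2_min: float = 0.90,
               split_age: Optional[float] = None
               ) -> tuple[pd.DataFrame, list]:
    """Average daily gain as the OLS slope of weight (kg) on age (days).

    Returns the slope in g/d with the regression R^2 per animal; animals
    with R^2 below ``r2_min`` are excluded and listed. With ``split_age``
    the first-period / second-period sub-slopes are reported as well.
    """
    rows, removed = [], []
    for animal, grp in weights.groupby("animal"):
        age = grp["age_days"].values.astype(float)
        w = grp["weight_kg"].values.astype(float)
        if len(age) < 2:
            raise ValueError(f"animal {animal}: at least 2 weight points required")
        if np.ptp(age) == 0:
            raise ValueError(f"animal {animal}: identical ages, slope undefined")
        slope, intercept = np.polyfit(age, w, 1)
        resid = w - (intercept + slope * age)
        sst = ((w - w.mean()) ** 2).sum()
        r2 = 1.0 if sst == 0 else 1.0 - (resid ** 2).sum() / sst
        rec = {"animal": animal, "adg_gpd": slope * 1000.0, "r2": r2}
        if split_age is not None:
            for name, mask in (("adg_first_gpd", age <= split_age),
                               ("adg_second_gpd", age >= split_age)):
                if mask.sum() >= 2 and np.ptp(age[mask]) > 0:
                    s, _ = np.polyfit(age[mask], w[mask], 1)
                    rec[name] = s * 1000.0
                else:
                    rec[name] = np.nan
        rows.append(rec)
        if r2 < r2_min:
            removed.append(animal)
    table = pd.DataFrame(rows)
    kept = table[~table["animal"].isin(removed)].reset_index(drop=True)
    return kept, removed


def parity_class(parity: int) -> int:
    """Dam parity classes: 1 -> 1, 2 -> 2, 3..7 -> 3, >= 8 -> 4."""
    if parity < 1:
        raise ValueError(f"parity must be >= 1, got {parity}")
    if parity <= 2:
        return int(parity)
    if parity <= 7:
        return 3
    return 4
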