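"""Synthetic herd generator: pedigree, LD-structured genotypes, phenotypes.

The generator is first-class code, not a test fixture: it produces data with
known truth (QTL positions and effects, breeding values, variance components)
so that every downstream stage — QC, relationship matrices, REML, the
association scan — can be checked for parameter recovery.

Linkage disequilibrium arises from a first-order Markov chain along each
founder chromosome (adjacent-marker correlation decaying exponentially with
physical distance) combined with the finite founder count; descendants are
produced by gene dropping with Poisson-distributed crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .config import SimConfig

MISSING = -1

PEDIGREE_COLUMNS = ["animal", "sire", "dam", "sex", "generation",
                    "birth_month", "dam_parity"]


@dataclass
class GenotypeData:
    """Genotypes for a set of animals as 0/1/2 alt-allele counts.

    ``calls`` is (n_animals, n_snps) int16 with -1 for missing.
    ``snp_map`` has columns snp_id, chrom, pos_bp (1-based inclusive).
    ``haplotypes``, when present, is the (2, n_animals, n_snps) phased
    matrix the calls were summed from (simulation output only).
    """

    calls: np.ndarray
    animal_ids: np.ndarray
    snp_map: pd.DataFrame
    haplotypes: Optional[np.ndarray] = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.animal_ids = np.asarray(self.animal_ids)
        if self.calls.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError("calls shape does not match animal_ids / snp_map")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def dosages(self) -> np.ndarray:
        """Float copy of calls with missing as NaN."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls."""
        d = self.dosages()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate_snp(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def call_rate_animal(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeData":
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        s = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        haps = None
        if self.haplotypes is not None:
            haps = self.haplotypes[:, a][:, :, s]
        return GenotypeData(
            calls=self.calls[np.ix_(a, s)],
            animal_ids=self.animal_ids[a],
            snp_map=self.snp_map.iloc[s].reset_index(drop=True),
            haplotypes=haps,
        )

    def copy(self) -> "GenotypeData":
        return GenotypeData(self.calls.copy(), self.animal_ids.copy(),
                            self.snp_map.copy(),
                            None if self.haplotypes is None else self.haplotypes.copy())


@dataclass
class TrueValues:
    """Ground truth of a simulated trait, kept for recovery tests."""

    qtl_ids: np.ndarray
    qtl_effects: np.ndarray
    breeding_values: np.ndarray
    sigma_a2_true: float
    sigma_e2_true: float


@dataclass
class MaskPattern:
    """Record of which calls were hidden when building LD/HD panels."""

    hd_animal_idx: np.ndarray
    overlap_snp_idx: np.ndarray
    masked_animal_idx: np.ndarray
    masked_snp_idx: np.ndarray


def simulate_pedigree(cfg: SimConfig) -> pd.DataFrame:
    """Multi-generation pedigree with discrete generations.

    Founders have unknown parents (coded 0); every later generation has
    ``cfg.n_founders`` offspring from random sire x dam matings within the
    previous generation. Sexes are assigned alternately and then shuffled,
    so both sexes exist even in tiny pedigrees. Output is topologically
    ordered by construction.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_f = cfg.n_founders
    records = []
    dam_offspring_count: dict[int, int] = {}

    def draw_sexes(n, rng):
        sexes = np.array(["M", "F"] * (n // 2 + 1))[:n]
        rng.shuffle(sexes)
        # tiny pedigrees must still contain both sexes to allow matings
        if n >= 2 and len(set(sexes)) == 1:
            sexes[0] = "M" if sexes[0] == "F" else "F"
        return sexes

    sexes = draw_sexes(n_f, rng)
    for i in range(n_f):
        records.append((i + 1, 0, 0, sexes[i], 0,
                        int(rng.integers(1, 13)), int(rng.integers(1, 11))))

    prev = list(range(1, n_f + 1))
    prev_sex = {records[i][0]: records[i][3] for i in range(n_f)}
    next_id = n_f + 1
    n_off = cfg.generation_size
    for g in range(1, cfg.n_generations + 1):
        males = [a for a in prev if prev_sex[a] == "M"]
        females = [a for a in prev if prev_sex[a] == "F"]
        if not males or not females:
            raise ValueError("impossible mating structure: a generation lacks one sex")
        sexes = draw_sexes(n_off, rng)
        gen_ids, gen_sex = [], {}
        for i in range(n_off):
            sire = int(rng.choice(males))
            dam = int(rng.choice(females))
            parity = dam_offspring_count.get(dam, 0) + 1
            dam_offspring_count[dam] = parity
            records.append((next_id, sire, dam, sexes[i], g,
                            int(rng.integers(1, 13)), parity))
            gen_ids.append(next_id)
            gen_sex[next_id] = sexes[i]
            next_id += 1
        prev, prev_sex = gen_ids, gen_sex

    return pd.DataFrame.from_records(records, columns=PEDIGREE_COLUMNS)


def _founder_haplotypes(rng, n_hap, freqs, pos, decay_bp):
    """Markov-chain haplotypes: corr(adjacent) = exp(-d / decay_bp)."""
    m = len(freqs)
    haps = np.empty((n_hap, m), dtype=np.int8)
    haps[:, 0] = rng.random(n_hap) < freqs[0]
    q = freqs * (1.0 - freqs)
    for j in range(1, m):
        rho = np.exp(-(pos[j] - pos[j - 1]) / decay_bp)
        if q[j - 1] <= 0 or q[j] <= 0:
            cond = np.full(n_hap, freqs[j])
        else:
            cond = freqs[j] + rho * np.sqrt(q[j] / q[j - 1]) * (haps[:, j - 1] - freqs[j - 1])
        np.clip(cond, 0.0, 1.0, out=cond)
        haps[:, j] = rng.random(n_hap) < cond
    return haps


def _gamete(rng, parent_haps, pos, chrom_starts, chrom_len, recomb_rate):
    """One recombinant gamete across all chromosomes.

    parent_haps: (2, n_snps) int8; pos: global position array; chrom_starts:
    slice bounds per chromosome into the SNP axis.
    """
    out = np.empty(parent_haps.shape[1], dtype=np.int8)
    for lo, hi in chrom_starts:
        n_x = rng.poisson(recomb_rate)
        start = int(rng.integers(2))
        if n_x == 0:
            out[lo:hi] = parent_haps[start, lo:hi]
            continue
        cuts = np.sort(rng.integers(1, chrom_len + 1, size=n_x))
        which = (start + np.searchsorted(cuts, pos[lo:hi])) % 2
        seg = parent_haps[:, lo:hi]
        out[lo:hi] = seg[which, np.arange(hi - lo)]
    return out


def simulate_genotypes(ped: pd.DataFrame, cfg: SimConfig) -> GenotypeData:
    """Gene-drop genotypes through a topologically ordered pedigree."""
    cfg.validate()
    if not (ped["animal"].values == np.arange(1, len(ped) + 1)).all():
        raise ValueError("pedigree must be topologically ordered with ids 1..n")
    rng = np.random.default_rng(cfg.seed + 1)
    m_per = cfg.snps_per_chromosome
    n_animals = len(ped)

    chroms, positions, freqs = [], [], []
    for c in range(cfg.n_chromosomes):
        pos = np.sort(rng.choice(cfg.chromosome_length_bp, size=m_per, replace=False)) + 1
        p = rng.uniform(cfg.founder_maf_low, cfg.founder_maf_high, size=m_per)
        flip = rng.random(m_per) < 0.5
        p = np.where(flip, 1.0 - p, p)
        chroms.append(np.full(m_per, c + 1))
        positions.append(pos)
        freqs.append(p)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions).astype(float)
    freq_arr = np.concatenate(freqs)
    n_snps = len(pos_arr)
    chrom_starts = [(c * m_per, (c + 1) * m_per) for c in range(cfg.n_chromosomes)]

    haps = np.zeros((2, n_animals, n_snps), dtype=np.int8)
    founders = ped.index[ped["sire"] == 0].values
    for c, (lo, hi) in enumerate(chrom_starts):
        fh = _founder_haplotypes(rng, 2 * len(founders), freq_arr[lo:hi],
                                 pos_arr[lo:hi], cfg.ld_decay_bp)
        haps[0, founders, lo:hi] = fh[0::2]
        haps[1, founders, lo:hi] = fh[1::2]

    id_to_row = {a: i for i, a in enumerate(ped["animal"].values)}
    for i, (sire, dam) in enumerate(zip(ped["sire"].values, ped["dam"].values)):
        if sire == 0:
            continue
        s_row, d_row = id_to_row[sire], id_to_row[dam]
        haps[0, i] = _gamete(rng, haps[:, s_row], pos_arr, chrom_starts,
                             cfg.chromosome_length_bp, cfg.recomb_rate)
        haps[1, i] = _gamete(rng, haps[:, d_row], pos_arr, chrom_starts,
                             cfg.chromosome_length_bp, cfg.recomb_rate)

    snp_map = pd.DataFrame({
        "snp_id": [f"snp_{c}_{p}" for c, p in zip(chrom_arr, pos_arr.astype(int))],
        "chrom": chrom_arr.astype(int),
        "pos_bp": pos_arr.astype(int),
    })
    calls = (haps[0].astype(np.int16) + haps[1].astype(np.int16))
    return GenotypeData(calls=calls, animal_ids=ped["animal"].values.copy(),
                        snp_map=snp_map, haplotypes=haps)


def _scaled_qtl_component(rng, dosages_centered, qtl_idx, sigma_a2):
    """Draw Gaussian QTL effects and rescale so var(Mq) is exactly sigma_a2."""
    q = rng.standard_normal(len(qtl_idx))
    a = dosages_centered[:, qtl_idx] @ q
    v = a.var()
    if sigma_a2 == 0.0 or v == 0.0:
        return np.zeros(len(qtl_idx)), np.zeros(dosages_centered.shape[0])
    s = np.sqrt(sigma_a2 / v)
    return q * s, a * s


def _fixed_effect_frame(ped: pd.DataFrame, cfg: SimConfig, rng) -> tuple:
    """Assign factor levels and draw per-level effects (sd 0.5 when >1 level)."""
    n = len(ped)
    n_cg, n_par, n_bm = cfg.fixed_effect_levels
    cg = rng.integers(1, n_cg + 1, size=n)
    if n_bm > 1:
        bm = ((ped["birth_month"].values - 1) % n_bm) + 1
    else:
        bm = np.ones(n, dtype=int)
    from .qc import parity_class
    if n_par > 1:
        par = np.array([parity_class(p) for p in ped["dam_parity"].values])
        par = np.minimum(par, n_par)
    else:
        par = np.ones(n, dtype=int)

    effect = np.zeros(n)
    for levels, n_lev in ((cg, n_cg), (par, n_par), (bm, n_bm)):
        if n_lev > 1:
            vals = rng.normal(0.0, 0.5, size=n_lev)
            effect += vals[levels - 1]
    return cg, par, bm, effect


def simulate_phenotypes(ped: pd.DataFrame, geno: GenotypeData,
                        cfg: SimConfig) -> tuple[pd.DataFrame, TrueValues]:
    """Polygenic + sparse-QTL trait: y = Xb + Mq + e.

    QTL effects are Gaussian, rescaled so the realized additive variance is
    exactly ``h2_true`` of a unit total variance; with ``sex_limited`` only
    males receive a phenotype (NaN otherwise).
    """
    cfg.validate()
    if (geno.calls == MISSING).any():
        raise ValueError("phenotype simulation requires complete genotypes")
    rng = np.random.default_rng(cfg.seed + 2)
    sigma_a2 = float(cfg.h2_true)
    sigma_e2 = 1.0 - sigma_a2

    d = geno.calls.astype(float)
    d_centered = d - d.mean(axis=0)
    qtl_idx = np.sort(rng.choice(geno.n_snps, size=cfg.n_qtl, replace=False))
    q, a = _scaled_qtl_component(rng, d_centered, qtl_idx, sigma_a2)

    cg, par, bm, fixed = _fixed_effect_frame(ped, cfg, rng)
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=len(ped)) if sigma_e2 > 0 else np.zeros(len(ped))
    y = fixed + a + e
    if cfg.sex_limited:
        y = np.where(ped["sex"].values == "M", y, np.nan)

    pheno = pd.DataFrame({
        "animal": ped["animal"].values,
        "sex": ped["sex"].values,
        "cg": cg,
        "parity_class": par,
        "birth_month": bm,
        "y": y,
    })
    truth = TrueValues(
        qtl_ids=geno.snp_map["snp_id"].values[qtl_idx],
        qtl_effects=q,
        breeding_values=a,
        sigma_a2_true=sigma_a2,
        sigma_e2_true=sigma_e2,
    )
    return pheno, truth


def simulate_phenotypes_bivariate(ped: pd.DataFrame, geno: GenotypeData,
                                  cfg: SimConfig, h2_pair=(0.3, 0.3),
                                  r_g: float = 0.7, r_e: float = 0.0
                                  ) -> tuple[pd.DataFrame, TrueValues, TrueValues]:
    """Two traits sharing the QTL set with genetic correlation ``r_g``."""
    cfg.validate()
    if (geno.calls == MISSING).any():
        raise ValueError("phenotype simulation requires complete genotypes")
    rng = np.random.default_rng(cfg.seed + 2)
    d = geno.calls.astype(float)
    d_centered = d - d.mean(axis=0)
    qtl_idx = np.sort(rng.choice(geno.n_snps, size=cfg.n_qtl, replace=False))

    cov = np.array([[1.0, r_g], [r_g, 1.0]])
    qq = rng.multivariate_normal(np.zeros(2), cov, size=cfg.n_qtl)
    truths, ys = [], []
    cg, par, bm, fixed = _fixed_effect_frame(ped, cfg, rng)
    e_cov = np.array([[1.0, r_e], [r_e, 1.0]])
    e_draws = rng.multivariate_normal(np.zeros(2), e_cov, size=len(ped))
    for t in range(2):
        sigma_a2 = float(h2_pair[t])
        sigma_e2 = 1.0 - sigma_a2
        a_raw = d_centered[:, qtl_idx] @ qq[:, t]
        s = np.sqrt(sigma_a2 / a_raw.var()) if a_raw.var() > 0 else 0.0
        a = a_raw * s
        e = e_draws[:, t] * np.sqrt(sigma_e2)
        y = fixed + a + e
        if cfg.sex_limited:
            y = np.where(ped["sex"].values == "M", y, np.nan)
        ys.append(y)
        truths.append(TrueValues(geno.snp_map["snp_id"].values[qtl_idx],
                                 qq[:, t] * s, a, sigma_a2, sigma_e2))

    pheno = pd.DataFrame({
        "animal": ped["animal"].values, "sex": ped["sex"].values,
        "cg": cg, "parity_class": par, "birth_month": bm,
        "y1": ys[0], "y2": ys[1],
    })
    return pheno, truths[0], truths[1]


def simulate_weight_series(ped: pd.DataFrame, cfg: SimConfig, n_points: int = 5,
                           age_start: float = 30.0, age_end: float = 360.0,
                           slope_mean: float = 1.0, slope_sd: float = 0.15,
                           intercept_mean: float = 40.0, intercept_sd: float = 5.0,
                           noise_sd: float = 2.0, high_noise_fraction: float = 0.1,
                           high_noise_sd: float = 40.0) -> pd.DataFrame:
    """Per-animal linear growth series: weight = intercept + slope * age + noise.

    A ``high_noise_fraction`` of animals receives very noisy series so that
    the downstream R^2 >= 0.9 cleaning rule has something to remove.
    Slopes are in kg/d (so a slope of 1.0 is an ADG of 1000 g/d).
    """
    if n_points < 2:
        raise ValueError("at least 2 weight points per animal are required")
    rng = np.random.default_rng(cfg.seed + 3)
    ages = np.linspace(age_start, age_end, n_points)
    rows = []
    for animal in ped["animal"].values:
        slope = rng.normal(slope_mean, slope_sd)
        intercept = rng.normal(intercept_mean, intercept_sd)
        sd = high_noise_sd if rng.random() < high_noise_fraction else noise_sd
        w = intercept + slope * ages + (rng.normal(0.0, sd, size=n_points) if sd > 0 else 0.0)
        for age, weight in zip(ages, w):
            rows.append((animal, float(age), float(weight)))
    return pd.DataFrame(rows, columns=["animal", "age_days", "weight_kg"])


def split_panels(geno: GenotypeData, hd_fraction: float,
                 ld_overlap_fraction: float, seed: int
                 ) -> tuple[GenotypeData, MaskPattern]:
    """Assign animals to high/low-density panels and mask non-overlap SNPs.

    Low-density animals keep only the ``ld_overlap_fraction`` subset of
    markers shared between the two platforms; the rest is set missing.
    """
    if not (0.0 < hd_fraction <= 1.0 and 0.0 < ld_overlap_fraction <= 1.0):
        raise ValueError("fractions must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_hd = max(1, int(round(hd_fraction * geno.n_animals)))
    hd_idx = np.sort(rng.choice(geno.n_animals, size=n_hd, replace=False))
    n_overlap = int(round(ld_overlap_fraction * geno.n_snps))
    overlap_idx = np.sort(rng.choice(geno.n_snps, size=n_overlap, replace=False))

    out = geno.copy()
    ld_idx = np.setdiff1d(np.arange(geno.n_animals), hd_idx)
    hidden_snps = np.setdiff1d(np.arange(geno.n_snps), overlap_idx)
    if len(ld_idx) and len(hidden_snps):
        out.calls[np.ix_(ld_idx, hidden_snps)] = MISSING
    pattern = MaskPattern(hd_animal_idx=hd_idx, overlap_snp_idx=overlap_idx,
                          masked_animal_idx=ld_idx, masked_snp_idx=hidden_snps)
    return out, pattern
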