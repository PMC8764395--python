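"""Configuration objects shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SimConfig:
    """Parameters of the synthetic herd generator.

    The defaults emulate a small dual-purpose cattle herd recorded at a
    performance-test station: a multi-generation pedigree, medium-density
    SNP panels with within-chromosome LD decay, a polygenic trait with a
    handful of larger QTL, phenotypes recorded on males only, and partial
    genotyping of the pedigree.

    Attributes
    ----------
    n_founders : int
        Animals in the base generation (unknown parents).
    n_generations : int
        Number of offspring generations appended after the founders; each
        generation has ``n_founders`` animals.
    n_chromosomes, snps_per_chromosome : int
        Genome layout; total markers = product of the two.
    chromosome_length_bp : int
        Physical length of every chromosome (bp).
    ld_decay_bp : float
        Length scale of the founder-haplotype Markov chain; the correlation
        between adjacent markers is exp(-distance / ld_decay_bp).
    recomb_rate : float
        Expected crossovers per chromosome per meiosis (Poisson mean).
    founder_maf_low, founder_maf_high : float
        Bounds of the uniform founder allele-frequency spectrum.
    n_qtl : int
        Number of markers carrying a non-zero effect on the trait.
    h2_true : float
        Narrow-sense heritability of the simulated trait, in [0, 1].
    sex_limited : bool
        If True only males receive phenotypes (performance-test design).
    prop_genotyped : float
        Fraction of animals carrying genotypes after panel assignment.
    fixed_effect_levels : tuple
        Number of levels for (contemporary group, dam parity class,
        birth month) fixed effects; a factor with one level has no effect.
    seed : int
        Seed for all randomness in the generator.
    """

    n_founders: int = 200
    n_generations: int = 3
    offspring_per_generation: int | None = None   # defaults to n_founders
    n_chromosomes: int = 5
    snps_per_chromosome: int = 400
    chromosome_length_bp: int = 100_000_000
    ld_decay_bp: float = 600_000.0
    recomb_rate: float = 1.0
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    n_qtl: int = 50
    h2_true: float = 0.3
    sex_limited: bool = True
    prop_genotyped: float = 0.6
    fixed_effect_levels: tuple = (10, 4, 12)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"h2_true must be in [0, 1], got {self.h2_true}")
        for name in ("n_founders", "n_chromosomes", "snps_per_chromosome",
                     "chromosome_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_qtl > self.n_chromosomes * self.snps_per_chromosome:
            raise ValueError("n_qtl exceeds the total number of SNPs")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if not 0.0 <= self.founder_maf_low <= self.founder_maf_high <= 0.5:
            raise ValueError("founder MAF bounds must satisfy 0 <= low <= high <= 0.5")
        if not 0.0 < self.prop_genotyped <= 1.0:
            raise ValueError("prop_genotyped must be in (0, 1]")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    @property
    def generation_size(self) -> int:
        return self.offspring_per_generation or self.n_founders

    @property
    def n_animals(self) -> int:
        return self.n_founders + self.generation_size * self.n_generations


@dataclass
class QcThresholds:
    """Quality-control thresholds, all on [0, 1] scales.

    ``maf_pre``/``callrate_snp_pre`` are the pre-imputation filters;
    the remaining marker/animal filters run after imputation.
    ``hwe_het_dev`` bounds the absolute deviation of the observed
    heterozygote proportion from its Hardy-Weinberg expectation 2pq.
    ``adg_r2_min`` is the minimum coefficient of determination of the
    weight-on-age regression for an animal's growth record to be kept.
    """

    maf_pre: float = 0.01
    callrate_snp_pre: float = 0.90
    maf_post: float = 0.05
    hwe_het_dev: float = 0.15
    callrate_snp_post: float = 0.90
    callrate_animal: float = 0.95
    adg_r2_min: float = 0.90

    def validate(self) -> None:
        for name in ("maf_pre", "callrate_snp_pre", "maf_post", "hwe_het_dev",
                     "callrate_snp_post", "callrate_animal", "adg_r2_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PipelineConfig:
    """End-to-end pipeline driver configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    blend_lambda: float = 0.99
    blend_beta: float = 0.01
    tune_mode: str = "mean-matching"   # or "none"
    alpha: float = 0.05
    p_nominal: float = 0.01
    enrich_fdr: float = 0.05
    enrich_min_genes: int = 3
    enrich_min_pct: float = 4.0
    seed: int = 0
    stages: tuple = ("simulate", "qc", "kinship", "reml", "gwas")


def load_pipeline_config(path) -> PipelineConfig:
    """PipelineConfig from a YAML file; `sim:` and `qc:` are nested maps."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw.pop("sim", {}).items()})
    qc = QcThresholds(**raw.pop("qc", {}))
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(sim=sim, qc=qc, **raw)
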