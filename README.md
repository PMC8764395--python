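# ssgwas

Single-step GBLUP association analysis for livestock herds.

`ssgwas` implements the full chain of a **single-step genome-wide
association study (ssGWAS)** of the kind used for growth and carcass traits
in cattle breeding programs where only part of the pedigree is genotyped
and phenotypes are sex-limited (e.g., recorded on performance-tested bulls
only). It is a library for Python users: the public API plus the short
narrative scripts in `examples/` are the interface.

## The model

Phenotypes follow the animal model

```
y = X b + Z a + e,      a ~ N(0, H σ²ₐ),   e ~ N(0, I σ²ₑ)
```

where **H** combines pedigree and genomic relationships through its inverse

```
H⁻¹ = A⁻¹ + [ 0  0 ; 0  G⁻¹ − A₂₂⁻¹ ]
```

with **A** the numerator relationship matrix, **A₂₂** its genotyped block
and **G** the allele-frequency-centered genomic relationship matrix
G₀ = MM′ / (2Σpᵢqᵢ), blended as G = λG₀ + βI (λ = 0.99, β = 0.01) and tuned
so its diagonal/off-diagonal means match A₂₂. Variance components come from
AI-REML (uni- and bivariate, with Monte-Carlo standard errors and HPD
intervals sampled from the inverse average-information matrix). Breeding
values of the genotyped animals are then linearly transformed into per-SNP
allele substitution effects

```
ĝ = λ δ [1/(2Σpq)] M′ G⁻¹ â₂₂
Var(ĝ) = λδ[1/(2Σpq)] M′G⁻¹ (Gσ̂²ₐ − C₂₂) G⁻¹M λδ[1/(2Σpq)]
```

with two-sided normal p-values pᵢ = 2(1 − Φ(|ĝᵢ/sd(ĝᵢ)|)). Genome-wide and
suggestive significance use the effective number of independent tests Mₑff
(eigenvalue decomposition of the SNP correlation matrix, integral +
fractional parts), and the scan is checked with the median-χ² inflation
factor. Post-GWAS steps map SNPs to genes within 15 kb, run hypergeometric
term enrichment with BH-FDR < 0.05 (≥3 genes, ≥4% of the term) and overlap
candidate regions with QTL interval tables.

A synthetic-herd generator (`ssgwas.simulate`) produces multi-generation
pedigrees, genotypes with within-chromosome LD decay, polygenic +
sparse-QTL traits with exact heritability, weight–age series for average
daily gain (ADG), and two-chip panel designs — all with known truth, so
every stage is testable for parameter recovery.

## Worked example

`python examples/association_scan.py` simulates a herd of 800 animals
(2,000 SNPs on 5 chromosomes) with a single large QTL and scans it:

```
h2 estimate: 0.268; inflation lambda: 0.918 (1 = well calibrated)
effective tests: 1141 of 2000 SNPs -> genome-wide -log10(p) threshold 4.36
true QTL at chr4:66575848
top hits (class = significant/suggestive):
        snp_id  chrom   pos_bp  minus_log10_p       class
snp_4_66575848      4 66575848      20.320190 significant
snp_4_66544244      4 66544244       4.596484 significant
snp_4_67137709      4 67137709       3.540657  suggestive
```

The REML heritability estimate is close to the simulated 0.30, the
inflation factor near 1 indicates the polygenic background is properly
absorbed by **H**, and the top hit is the causal marker itself; the
Bonferroni-style threshold uses the 1,141 effective tests rather than the
raw 2,000 markers. The other example scripts cover herd simulation, QC and
LD decay, relationship matrices, uni/bivariate REML, post-GWAS enrichment
and the one-call pipeline driver (`ssgwas.pipeline.run_pipeline`).

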