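# Methods

This note documents the statistical machinery in `ssgwas`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about behaviour on real herds.

## Single-step model and relationship matrices

The core model is the animal model `y = Xb + Za + e` with
`a ~ N(0, H σ²ₐ)`. Fixed effects are categorical (contemporary group, dam
parity class mapped to {1, 2, 3–7, ≥8} → {1,2,3,4}, birth month). For
identifiability the first factor enters at full rank and every later factor
drops its first level; pivoted QR removes any residual collinearity. REML
estimates are invariant to this choice (tested).

`A` is built by the tabular recursion (a_ii = 1 + 0.5·a_sd), and `A⁻¹` by
Henderson's rules with inbreeding, using Mendelian-sampling variances
`d_i = 1 − 0.25 Σ(1 + F_parent)`. Inbreeding coefficients are read off the
tabular `A`, which is O(n²) memory; the package targets desk-scale
pedigrees (up to a few thousand animals), where this is the simplest
correct route.

`G₀ = MM′/(2Σpᵢqᵢ)` is centered by the allele frequencies of the current
genotyped set by default (user-supplied frequencies are accepted; note that
observed-frequency centering makes `G₀` structurally singular, rank ≤ n−1,
because centered rows sum to zero — this is why blending is not optional).
Blending uses λ = 0.99, β = 0.01. Tuning to the pedigree base offers two
outputs computed together: the mean-matching adjustment `G_adj = α + γG`
(solving the two-equation system on diagonal and off-diagonal means), which
is what is actually applied to `G`, and the scalar
`δ = 1 − (0.5/n²)(ΣΣA₂₂ − ΣΣG)`, which is carried into the back-solve as a
multiplier. δ multiplies `ĝ` linearly; a square-root convention would be
equally defensible, and the parameter is exposed so either can be supplied.
With no genotyped animals `H⁻¹ = A⁻¹` exactly; with `G_adj = A₂₂` the
single-step solutions collapse to pedigree BLUP (both tested).

## AI-REML

Variance components are estimated on the phenotypic covariance
`V = Σ θₖ Bₖ` with the usual average-information update
`θ ← θ + AI⁻¹ s`, `sₖ = −½[tr(P Bₖ) − y′P Bₖ P y]`,
`AIₖₗ = ½ (Bₖ P y)′ P (Bₗ P y)`. Starting values are var(y)/2 per
component; convergence is a relative parameter change below 1e-8 (1e-6
bivariate) within 200 iterations, error with trace otherwise. When an AI
step proposes a non-positive variance the univariate sampler takes an exact
EM step (`θ ← θ + θ²/q · [y′P B P y − tr(P B)]`), which cannot leave the
parameter space. The bivariate sampler instead halves the AI step until
admissible and projects the 2×2 genetic and residual blocks back to the PD
cone by eigenvalue clipping ("bending"); the flag recorded per iteration in
the trace marks where this happened. Residual covariance between traits is
attached to record pairs of the same animal, so unequal record sets are
handled. Dense V is used throughout: with records in the low thousands a
Cholesky per iteration is cheap and removes a whole class of sparse-solver
edge cases.

Monte-Carlo standard errors sample parameter vectors from
`N(θ̂, AI⁻¹)`, reject draws with non-positive variances (error above 50%
rejection), and report the SD and the shortest 95% interval (HPD) of each
derived quantity (h², genetic/phenotypic correlations). A correlation is
"significant" when its HPD excludes zero. Phenotypic covariance is defined
as genetic + residual.

## Back-solved SNP effects and testing

`ĝ = λδ[1/(2Σpq)] M′G⁻¹ â₂₂` with
`Var(ĝ) = (λδ/(2Σpq))² · diag(M′G⁻¹(Gσ̂²ₐ − C₂₂)G⁻¹M)`, where `C₂₂` is the
genotyped block of the inverse mixed-model coefficient matrix scaled by
σ̂²ₑ so that `PEV(â₂₂) = C₂₂`. Diagonal values below −1e-10 (relative)
raise a scale-mismatch error; smaller negatives are clipped to zero and the
affected SNPs are excluded from testing (p reported as NA) rather than
assigned p = 0. The per-SNP variance explained is reported as
`100·2pq·ĝ²/σ̂²ₐ`, the standard genic-variance share (the formula is stated
in the output header since conventions differ).

The effective number of tests is the eigenvalue decomposition rule
`Mₑff = Σ[1(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)]` applied to the SNP correlation matrix
per chromosome (optionally in fixed-size blocks) and summed; near-integer
eigenvalues are snapped within 1e-9 so the fractional part is numerically
stable. The genome-wide threshold is α/Mₑff; the suggestive threshold is
1/Mₑff (one expected false positive per scan), with 0.1/Mₑff selectable.
Boundary hits (p exactly at a threshold) count as the stronger class.
Inflation is `median(χ²)/0.45494` from the two-sided p-values.

## Post-GWAS

SNPs map to every gene whose interval lies within 15 kb (1-based inclusive
coordinates; gap 0 with a "within" flag when inside; nearest genes flagged
with ties kept). The mapping uses gene spans, not CDS sub-features. The
enrichment background is every gene with ≥1 mapped SNP; hits are genes with
≥1 SNP at nominal p < 0.01, each gene counted once. Terms are tested with
the one-sided hypergeometric tail against the background, BH-adjusted
jointly across terms; a term passes at FDR < 0.05 with ≥3 overlapping genes
covering ≥4% of the term's background genes (the percentage denominator is
the term∩background size). Candidate regions are SNP ± flank; interval
overlap requires ≥1 shared bp. Localized LD around a focal SNP uses ±0.5 Mb
and the five r² classes with boundaries assigned to the lower class.

## Synthetic herds

The generator emulates a small dual-purpose herd: discrete generations of
constant size; founder haplotypes from a first-order Markov chain whose
adjacent-marker correlation decays as `exp(−d/L)` with L = 600 kb, plus
gene dropping with Poisson(1) crossovers per 100 Mb chromosome — together
these reproduce the qualitative LD regime of a real medium-density panel
(mean r² ≈ 0.12–0.17 below 1 Mb, near zero beyond; the level below 1 Mb
depends on the marker spacing, so it is a regime match, not a calibrated
value). Founder frequencies are uniform on [0.05, 0.5] (mean MAF ≈ 0.28).
Defaults are 200 founders × 3 generations (800 animals) and 5 × 400 SNPs —
a deliberate scale-down of a real cattle design (tens of thousands of
markers on 29 autosomes) chosen so a full scan runs in seconds. QTL effects
are Gaussian and rescaled so the realized additive variance is exactly
h²·1.0, making recovery targets sharp; fixed-effect levels get N(0, 0.5²)
values; sex-limited recording leaves females without records. The trait
variance is on a unit scale, not in trait units (kg, g/d, points);
weight-age series for ADG are generated separately in kg and days with ADG
reported in g/d.

What the generator does not emulate: coalescent-accurate LD and allele
frequency spectra, selection or assortative mating, genotyping error,
maternal or permanent-environment effects. Passing tests therefore show the
estimators are correct under the stated model, not that real-data
complications (selection bias, hidden structure, platform artifacts) are
handled.

## Test and acceptance problem sizes

Calibration and recovery checks run at the scale the generator defaults
define: null-scan calibration on 10 herds of 800 animals × 2,000 SNPs with
a fully polygenic trait (every marker causal — the correct null for a
PEV-standardized statistic); heritability recovery at 2,000 animals
(~1,000 records) × 10 seeds per h² level; bivariate recovery of r_g = 0.7
at the same size; localization on single-QTL herds of 800. The imputation
cross-validation baseline (parental average, else per-SNP mean) is a
deliberately simple reference — its accuracy (~0.75 on the default design)
is a floor for any real imputation software, and the harness accepts any
imputer callable.

## Known limitations

Dense linear algebra bounds practical size to a few thousand genotyped
animals; no metafounders or unknown-parent groups; no multi-trait (>2)
models; no iterative SNP reweighting; conflict resolution blanks the
offspring call (the parent's genotype is usually supported by more
descendants), which is one of several defensible rules.
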