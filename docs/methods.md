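# Methods

This note documents the statistical models implemented in `hipgwas`, the
choices made where the design was genuinely open, and what the synthetic
cohort generator does and does not emulate.

## Phenotype model

A dog's phenotype is an ordered pair of FCI hip grades (A–E, one per hip).
Classification is total and deterministic over all 25 pairs: A/A → control;
any B → excluded (borderline scores confound the control set); C/C → mild
case; both hips dysplastic with at least one D or worse → moderate-to-severe;
one normal and one dysplastic hip → excluded as ambiguous (the source data
excluded such dogs; neither case nor control is defensible). Three nested
case definitions are supported: strict (both hips D or worse) ⊂
moderate-to-severe ⊂ relaxed (mild ∪ moderate-to-severe).

## Quality control

Filter order is fixed and documented because removal counts depend on it:
autosome restriction → per-SNP call rate (≥ 0.95) → per-sample call rate
(≥ 0.90, computed over surviving SNPs) → MAF (≥ 0.05) → Hardy–Weinberg on
controls only (Pearson 1-df χ², p ≥ 1e-5). HWE is restricted to controls
because trait-associated SNPs may legitimately deviate among cases. The
χ² test (not the exact test) is the default at these sample sizes
(~280 controls); an exact-test option exists behind a flag. Manual sample
exclusions (e.g. an outlier genotype) are an explicit id list, not a rule.
Batch merging reconciles strand by complementing allele labels where the
pairs are reverse complements; A/T and C/G SNPs cannot be disambiguated from
labels and are dropped when discordant.

## Population structure

The GRM averages allele-frequency-standardized genotype products over SNPs
(missing calls mean-imputed for this computation only). Classical MDS is
applied to the kinship-induced distance `d_ij = √(k_ii + k_jj − 2k_ij)`;
because the double-centered squared-distance matrix equals the centered
kinship, coordinates come directly from the eigendecomposition of JKJ.
Subpopulation labels come from a Gaussian mixture on the top two MDS axes
with the component count chosen by BIC over 1..k_max. This replaces
covariance-parametrized model-based clustering with the same selection
principle (BIC) while staying inside scikit-learn; two axes is the default
because the cluster structure of interest is two-dimensional
(show/working/mixed lines), and the axis count is configurable since the
original analysis does not state how many dimensions fed its clustering.

## Association statistics

`trend_score_test` is the Cochran–Armitage trend test with scores (0,1,2);
with covariates it generalizes to the logistic score test for adding the
genotype to the null model (without covariates the two coincide exactly,
T = N·corr²(g, y)). The scan-level variant uses the linear score form on
OLS residuals with the ML variance, which is numerically identical without
covariates and vectorizes over SNPs.

`fit_polygenic` fits y = Xβ + g + e with cov(g) = σ²_g K by maximum
likelihood, profiling over h² on the eigenbasis of K (grid + bounded
refinement; the profile is smooth in practice). The binary phenotype is
treated as quantitative 0/1, mirroring the score-test methodology this
mirrors; the environmental residuals `ê = σ²_e V⁻¹(y − Xβ̂)` are
exchangeable under the null and are the permutation currency.
`mm_score_test` computes `T = (g̃ᵀV⁻¹r)²/(g̃ᵀV⁻¹g̃)` with g̃ residualized
against the fixed effects in the V-metric; with K = I it reduces to the
trend test (V ∝ I for any h², so the identity is exact).

Genomic control divides every statistic by λ = median(T)/χ²₁,₀.₅
unconditionally: deflation (λ < 1) is corrected upward the same way
("reverse GC") rather than clamping λ at 1. Empirical genome-wide p-values
permute the residual vector, record the per-permutation maximum statistic,
and use the (1 + b)/(n_perm + 1) estimator; exhaustive enumeration replaces
sampling for small binary vectors. simpleM operates per chromosome in
windows of 1000 SNPs with variance fraction C = 0.995 (the published
defaults; the source analysis states neither).

## LD and clumping

r² between two unphased SNPs comes from EM haplotype frequencies under HWE
(the double heterozygote is the only ambiguous cell; convergence at 1e-8 or
1000 iterations, composite genotype correlation as a flagged fallback).
Clumping is greedy: the most significant unassigned SNP passing the p
threshold (default 5e-5, the permissive end of the stated 5e-5–5e-6 range)
indexes a clump and absorbs unassigned same-chromosome SNPs within 7.5 Mb
at r² ≥ 0.7. Ties in p break by genomic position (smaller coordinate
first).

## Regional CMH and the segregation screen

The CMH statistic uses allelic 2×2 tables stratified by genotyping batch,
1 df, no continuity correction. The per-stratum variance is
r₁r₂c₁c₂/n³, which makes the single-stratum statistic exactly the Pearson
χ² and makes M² invariant to collapsing identical strata; the classical
hypergeometric variance (n²(n−1)) is available as an option and is the
cross-check against statsmodels. Zero-margin strata carry no information
and are dropped. Family-wise significance permutes case/control labels
within strata — preserving the batch structure the CMH conditions on — and
compares each observed M² to the null distribution of the maximum;
enumeration is exact when the number of distinct within-strata assignments
is small.

The screen retains annotated variants with |case carriers − control
carriers| ≥ 22 outside the intergenic/intronic/synonymous classes, carrier
defined as ≥ 1 alternate allele (an allele-count mode exists behind a
flag). Negative differences (control-enriched, candidate protective) are
preserved, and per-gene × effect-class rollups sum signed differences over
all non-excluded variants of genes with at least one retained variant.

## Contingency analyses and risk models

Odds ratios use Woolf (log-normal) intervals; a single zero cell triggers
Haldane–Anscombe +0.5 on all cells (flagged), two zero cells in a margin
leave the OR undefined. The Spearman interval is plain Fisher-z,
tanh(atanh ρ ± 1.96/√(n−3)), without variance inflation — this choice
reproduces the published interval [0.56, 0.71] at ρ = 0.64, n = 253.

The risk models are nested logistic GLMs (IRLS via statsmodels): the full
model carries two deletion indicators (one allele; both alleles) plus an
indicator for the protective homozygous combined SNP genotype, the reduced
model drops the deletion terms. The deletion enters as two indicators
rather than an additive dosage because the published coefficients are
reported per level. Comparison is twofold: Δdeviance against χ² with the
df difference, and the paired DeLong test with placement-value covariance.
The DeLong p is one-sided (upper tail): the published (Z, P) pairs —
(1.31, 9.5e-2), (2.71, 3.3e-3), (3.59, 1.6e-4) — are consistent only with
that convention. Whether covariates entered the published GLMs is unstated;
the default here is none (matching the published variable list), and the
design matrix is caller-supplied so covariates can be added.

## Synthetic cohort generator

The generator is the test bed for everything above. Per-cluster allele
frequencies drift from block-shared ancestral frequencies under the
Balding–Nichols model (default Fst 0.05, 4 clusters). Haplotypes copy the
previous allele within an LD block with probability 0.98 (adjacent-SNP
allelic correlation ≈ the copying rate, putting within-block r² at roughly
0.70–0.96, the moderate-to-high range observed within real associated loci
on these arrays) and two independent haplotypes form
each diplotype, so HWE holds exactly within clusters while pooled data show
the Wahlund-style structure the GRM/cluster covariates must absorb. Disease
is a logistic liability: per-risk-allele log-odds at the planted loci
(defaults: a protective locus OR 0.4 and a risk locus OR 2.3 on one
chromosome, > 7.5 Mb apart) plus cluster intercepts spanning 1.0 on the
log-odds scale; the base intercept is solved so the expected case fraction
matches 247/526. Hip scores map back deterministically (controls A/A, mild
C/C, moderate-to-severe pairs split to match a 132/168 strict fraction);
5% of dogs receive a B score and drop out. Batches are round-robin and
missingness independent at 1%.

The deletion locus is a Gaussian copula: a latent normal correlated with
the tag genotype's latent is discretized at the published genotype
frequencies (0.43/0.44/0.13), with the latent correlation calibrated so the
*population* Spearman coefficient of the two discrete variables (computed
exactly from bivariate-normal rectangle probabilities) equals the target
(default 0.65); |ρ| = 1 short-circuits to a monotone relabelling. The
annotated variant catalogue emulates a targeted-resequencing screen of
opposing-homozygote pools: ~2% of variants ride the selected haplotypes and
segregate almost completely (carrier probabilities 0.97 vs 0.01), the rest
share a common frequency in both groups.

What the generator does not emulate: genotyping-platform error modes and
batch-specific cluster-calling artifacts, pedigree loops beyond GRM-level
relatedness, mutation processes at the repeat locus, and real LD decay
(blocks are rectangular with geometric within-block decay). Passing tests
therefore demonstrate correctness and calibration of the statistics under
the stated stochastic structure, not robustness to array-specific
artifacts.

## Problem sizes and numerical choices

The default synthetic genome is 2000 SNPs across 5 chromosomes for 525
dogs — large enough for stable genomic-control medians, clumping and
permutation nulls while keeping the full pipeline in seconds; tests and the
acceptance script use 500–10,000 permutations depending on the resolution
each check needs. EM convergence is 1e-8; the polygenic likelihood is
profiled on a 25-point grid refined by bounded scalar minimization;
non-PSD kinships are repaired by spectrum shifting with a warning;
permutation estimators use (1 + b)/(n + 1) so no p is exactly zero.

## Known limitations

* The mixed-model fit treats the binary trait as quantitative (as does the
  methodology it mirrors); a logistic-covariate-only fallback exists but no
  liability-scale GLMM.
* The published permutation counts (e.g. 24159) are accepted as
  configuration values; their relation to effective-test estimates is an
  input, not derived.
* Exact conditional (non-Woolf) intervals are available only for 2×2
  tables; no exact logistic regression.
* X-chromosome handling and imputation are out of scope (autosomes only).
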