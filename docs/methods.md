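# Methods

`famassoc` implements a joint-association analysis for quantitative traits
measured in multiplex families: per-SNP family-based score tests with
covariate adjustment, combination of the per-SNP p-values into gene-level
and gene-family-level evidence by the weighted truncated product method
(wTPM) with a Monte Carlo null that respects linkage disequilibrium (LD),
and Storey q-value control of the false discovery rate. A synthetic-study
generator supplies multiplex pedigrees, LD-structured genotypes and
right-skewed correlated traits with known ground truth, so every stage of
the pipeline can be validated without access to restricted individual-level
data.

## Single-SNP family-based test

For each nuclear family with both parents genotyped, offspring genotypes
(additive minor-allele counts `X`) are compared with their Mendelian
expectation given the parental genotypes, weighted by the offspring's trait
residual `T`:

    U = Σ_fam Σ_j T_j (X_j − E[X_j | parents])
    V = Σ_fam Σ_j T_j² Var(X_j | parents)
    Z = U / √V,   p = 2(1 − Φ(|Z|))

Under additive coding the conditional moments have the closed form
`E[X|f,m] = f/2 + m/2` and `Var(X|f,m) = (f/2)(1−f/2) + (m/2)(1−m/2)`.
Conditioning on parental genotypes makes the test robust to population
stratification; the randomness under the null is the transmission, not the
trait, so the test remains valid when traits are correlated within
families. Extended pedigrees are decomposed into nuclear units treated as
independent contributions — the same first-order treatment the FBAT
program applies, and exact for the null mean and variance because a
transmission is mean-zero conditional on its own parents regardless of
what was transmitted one generation up.

Residuals `T` are ordinary-least-squares residuals of the log-transformed
trait on the covariate design (categoricals expanded to indicators);
the offset subtracted is the fitted mean, so residuals are centered over
the regression sample. Families with a missing parental genotype are
skipped rather than reconstructed (no sufficient-statistic algorithm for
missing parents; the generator emits complete parents, and the module
boundary leaves room to add one). A per-SNP effect-size proxy `b = U/V`
is exported; a SNP needs at least `min_informative` (default 10)
informative families — families whose conditional variance contribution is
positive — to receive a p-value.

## Truncated product combination and its Monte Carlo null

The gene-level statistic over a gene's `L` p-values with non-negative
weights `w` (mean 1 within the gene) and truncation threshold `τ` is

    W = Π_i p_i ^ (w_i · 1[p_i ≤ τ])

with the empty product equal to 1. All products are computed in the log
domain (61 p-values of 1e-300 combine without underflow). `τ` defaults to
0.05, the canonical truncation for this statistic; it is exposed in
configuration. Significance is assessed against `B` Monte Carlo draws
(default 50,000; the test suite uses 2,000): `Z_b ~ MVN(0, R)` with `R`
the LD correlation matrix of additive genotype codes estimated over
founders (pairwise-complete, cross-chromosome entries zero by
construction, eigenvalue-clipped to the nearest positive-semidefinite
correlation matrix when sampling noise requires it), converted to
two-sided p-values and combined with the same statistic. The reported
p-value is the add-one estimator `(1 + #{W_b ≤ W_obs}) / (B + 1)`, never
zero and never below `1/(B+1)`.

**Effect-size weights.** With `weight_mode = "abs_effect"` (the default),
the observed weights are `|b_i| = |U_i/V_i|` normalized to mean 1 within
the gene. Because `|b_i| = |Z_i|/√V_i` is a deterministic function of the
test's own Z-score, the weights are correlated with the p-values they
multiply; evaluating the null draws with the observed weights frozen makes
the observed statistic stochastically smaller than the null ones and
inflates type-I error severely (measured gene-level rejection 0.13 and
family-level 0.23 at nominal 0.05). The null draws therefore re-estimate
their own weights through the same map, `w_bi ∝ Φ⁻¹(1 − p_bi/2)/√V_i`
with the observed `V_i` held fixed — the weight-estimation step is
replicated inside the null, restoring exchangeability (measured rejection
0.031/0.040 under identical conditions). The observed weights are still
recorded in the gene result for reporting.

**Gene-family stage.** The second stage reuses the same SNP-level
ensemble instead of nesting Monte Carlo loops: for every draw `b`, each
gene's null statistic is converted into a null gene-level p-value by its
rank among all `B` draws for that gene, and the unweighted truncated
product over genes is formed draw by draw; the family p-value is again the
add-one count against the observed statistic (observed gene p-values come
from the gene stage). Reusing one ensemble preserves the between-gene
correlation of genes in the same genomic cluster at `B` rather than `B²`
cost.

For the unweighted, independent-null case the distribution of `W` has a
closed form (Zaykin's formula), implemented in the log domain. It serves
purely as an analytic cross-check of the Monte Carlo machinery; tests
verify agreement within Monte Carlo error at `L ∈ {2, 7, 61}`.

## Multiple-testing control

Storey's q-value: `π̂0(λ) = #{p > λ}/(m(1−λ))` over λ = 0.05…0.95 (step
0.05), smoothed by a degree-3 least-squares polynomial and evaluated at
the largest λ, clamped to (0, 1]; with fewer than 10 p-values the
conservative `π̂0 = 1` is used, at which point the q-values coincide
exactly with Benjamini–Hochberg adjusted p-values (property-tested). The
significance flag uses q < 0.05. Correction defaults to per-trait scope
(61 tests) with a switch for joint correction across traits.

## Synthetic studies

The generator emulates a family study of ~94 multiplex families totalling
~3,700 members, 61 tagSNPs in 7 gene blocks, and four obesity traits (BMI,
waist circumference, waist-to-hip ratio, percent body fat).

* **Founder haplotypes** are drawn by thresholding a latent multivariate
  normal vector at the quantile of each SNP's target minor-allele
  frequency. Within a block the latent correlations form an AR chain whose
  adjacent entries are solved numerically (Brent's method on the
  bivariate-normal orthant probability) so the *allelic* correlation of
  each adjacent pair matches the target `r` (default 0.6); blocks are
  independent. Default frequencies vary between 0.11 and 0.42, similar
  within a block — both realistic for tagSNPs and necessary for the target
  correlation to be attainable between binary variables.
* **Pedigrees** are three-generation multiplex families: a grandparental
  couple whose children (one per subsequent nuclear unit, 5–7 units per
  family) each pair with a marry-in founder and have 4–7 children. This
  yields ≈3,660–3,760 members over 94 families, matching the emulated
  study's scale.
* **Gene drop**: founders receive pool haplotypes; each meiosis transmits
  a recombinant with per-interval crossover probability equal to the
  recombination fraction (0.01 within blocks, 0.5 across block
  boundaries).
* **Traits** are generated on the log scale: intercept + covariate effects
  (age, sex, center, smoking, alcohol, activity, energy intake, a 3-level
  ordinal socioeconomic score, diabetes) + Σ β·genotype + a family random
  effect (variance 0.02) + noise (variance 0.04), then exponentiated, so
  observed traits are right-skewed and the pipeline's log transformation
  recovers linearity. Raw weight/height/waist/hip fields are emitted so
  BMI and WHR are recomputable. One seed drives everything through
  per-stage sub-streams, so stages can be regenerated independently and a
  fixed seed reproduces the study byte for byte.

What the generator does **not** emulate: coalescent or demographic
realism, cross-gene LD within the chromosome-15 cluster, genotyping error
and missingness patterns, assortative mating, trait-specific residual
variances, or calibrated between-trait correlations (the traits share
covariate and family components but their residual correlation is not
tuned to any real cohort). Passing tests therefore demonstrate the
statistical machinery is correct under a faithful family design, not that
the generator reproduces any particular cohort's data.

## Operating characteristics (measured by the test suite)

* **Type-I error**: under the global null (200 nuclear families with 2–4
  offspring, 61 SNPs with block LD, B = 2,000), pooled single-SNP,
  gene-level and gene-family rejection rates at α = 0.05 over 1,000
  replicates fall inside exact binomial 95% intervals. Pooling over the 61
  SNPs / 7 genes of each replicate lowers the estimator's variance, so the
  binomial interval at the replicate count is conservative.
* **Joint-association power**: with three causal SNPs (β = 0.016 per
  minor allele on the log-trait scale, calibrated to ≈30% single-SNP power
  at α = 0.05) in the five-SNP gene CHRNA4, the gene-family p-value beats
  0.05 more often than the best single SNP survives a Bonferroni
  correction over all 61 SNPs (measured ≈0.14 vs ≈0.10 over 300
  replicates) — the signature of variants that associate jointly while
  none survives multiple-testing correction individually. A
  majority-causal small gene is the regime the joint method targets; the
  advantage over Bonferroni narrows when the same total signal is spread
  thinly across a 16-SNP gene.

## Numerical and design notes

* Monte Carlo p-values use the add-one estimator; the granularity is
  `1/(B+1)` (2.0e-5 at B = 50,000).
* `tpm_statistic` applies supplied weights literally; normalization to
  mean 1 is performed where effect-size weights are constructed.
* Monomorphic SNPs get identity rows in `R` with a warning; Mendelian
  inconsistencies on file read are set missing and counted rather than
  fatal.
* The minor allele is determined from founders only (ties broken
  lexicographically), so offspring transmissions cannot bias the coding;
  swapping the coding flips the sign of Z and leaves p unchanged.
* Sensitivity variants mirror the published analyses: diabetes-case
  exclusion (the diabetes covariate is then dropped as constant), smoking
  adjustment toggled, BMI added as a covariate for non-BMI traits, and the
  globally most significant SNP removed.
* Reduced problem sizes in the test suite (B = 2,000, 200 nuclear
  families) are the package's validation design; `B = 50,000` remains the
  default for a real `run`.

## Known limitations

* No Rabinowitz–Laird sufficient-statistic handling of missing parents; no
  haplotype or dichotomous-trait tests; no empirical-variance mode.
* Normal-approximation p-values only; with few informative families the
  per-SNP test relies on `min_informative` as a guard rather than an exact
  small-sample null.
* The LD matrix is estimated and then treated as known by the Monte Carlo
  null; with very few founders this understates uncertainty.
* The published analysis's exact weight definition and truncation
  threshold are not stated in the source material; `abs_effect` weighting
  and τ = 0.05 are documented defaults, with no claim of reproducing the
  original tables numerically.
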