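# Methods

This note documents the statistical model behind `targetmr`, the
assumptions and defaults of its synthetic-study generator, the numerical
choices made where the design was open, and what the shipped tests do
and do not establish about real data.

## The causal model

Drug-target MR treats genetic variants in or near a drug-target gene
that alter the drug's biomarker as lifelong, randomized proxies for
pharmacological modulation of the target. Three instrumental-variable
assumptions are required: *relevance* (variants associate with the
biomarker — directly screened via F = β²/SE² and the GRS partial R²),
*independence* (no confounding of the variant-outcome association —
probed by covariate balance across GRS tertiles), and *exclusion
restriction* (variants affect outcomes only through the biomarker — not
directly testable; the diagnostics report always states this).

Let dⱼ ∈ [0,2] count the LDL-lowering allele of instrument j and
wⱼ = |βⱼ^ext| its external GWAS weight. The score G = Σⱼ wⱼ dⱼ yields,
for each standardized outcome Y and with covariates C (age, sex, 6
ancestry PCs),

    β̂_wald = β̂(Y ~ G | C) / β̂(LDL_std ~ G | C),  SE = SE_num / |β̂_den|,

reported per SD-decrease in LDL-C (sign flipped), with a normal
reference. The first-order delta-method SE ignores denominator
variance; this is standard when F > 10 and the pipeline flags weaker
denominators. Note that in a one-sample design the numerator and
denominator errors are positively correlated, so these intervals are,
if anything, slightly conservative for the ratio.

For the summary-statistic arm with exposure betas bₓ, outcome betas b_y,
outcome SEs s, and reference LD correlations ρ, the correlated-variant
IVW estimate is GLS through the origin with Ω = (s sᵀ) ∘ ρ:

    β̂ = (bₓᵀ Ω⁻¹ b_y)/(bₓᵀ Ω⁻¹ bₓ),  SE = (bₓᵀ Ω⁻¹ bₓ)^(-1/2),
    Q  = rᵀ Ω⁻¹ r,  r = b_y − β̂ bₓ,  df = k−1.

Ω is factorized (Cholesky), never inverted explicitly; an ill-conditioned
Ω (condition number > 1e8) raises with advice to clump more strictly
rather than silently regularizing, because clumping at r² < 0.3 should
prevent the situation.

## Attrition correction

Item missingness is imputed by chained-equations predictive mean
matching: per variable, a Bayesian draw of the regression parameters
(σ² from a scaled inverse-χ², coefficients from the normal posterior),
type-1 matching of each missing case to its k = 5 nearest observed
donors on the predicted mean, and a uniform donor draw; 10 sweeps when
predictors themselves contain missingness, one exact sweep otherwise
(the conditionals then do not interact). m = 50 imputations by default.
The PMM engine is written against an explicit `numpy.random.Generator`
so one master seed reproduces the ensemble exactly; statsmodels provides
the ordinary OLS/WLS/logistic fits everywhere else.

Participation weights come from a logistic response model on fully
observed predictors; responder weights 1/p̂ are truncated at their
1st/99th percentiles and normalized to mean 1. Truncation trades a
small residual bias for a large variance reduction under strong
selection (we verified the untruncated estimator is unbiased but
noisier); the truncation quantiles are configurable.

MI and IPW are combined by fitting the weighted analysis model within
each completed dataset — weights computed once from fully observed
baseline predictors and reused across imputations — and pooling the
per-imputation Wald estimates by Rubin's rules: q̄, W̄, B,
T = W̄ + (1+1/m)B, with Barnard–Rubin degrees of freedom when the
complete-data df is known and the classical (m−1)(1 + W̄/((1+1/m)B))²
otherwise. Outcome standardization uses the observed (pre-imputation)
mean/SD applied uniformly across imputations so the estimand scale is
fixed.

## Multiplicity and power

The outcome panel is highly redundant (overlapping lipoprotein
measures), so the Bonferroni denominator is the effective number of
tests: the smallest k whose top-k eigenvalues of the outcome correlation
matrix reach 99% of total variance. Correlations are pairwise-complete
(computed before imputation); if estimation noise breaks positive
semi-definiteness the matrix is projected by eigenvalue clipping at
zero. The corrected threshold α/n_eff is reported at full precision.

Detectable effects use the non-centrality closed form
|β| = (z₁₋α/₂ + z_pow)/√(nR²) and, for a case-control outcome with case
fraction K, |ln OR| = (z₁₋α/₂ + z_pow)/√(N R² K(1−K)), returning the
protective OR exp(−|ln OR|). This parameterization reproduces its own
numeric power inversion to 1e-6. Published calculators for the same
design add variance-inflation terms we do not model, so continuous-
outcome detectable betas from other tools can differ; the formula and
its inputs are always exposed.

## The synthetic study generator

The generator defines the study conditions under which the package is
validated. Defaults (one master seed; independent sub-streams per
component so toggling one component does not shift the others):

* **Exposure GWAS**: n = 146,492; per-variant marginal betas are the LD
  projection of joint effects, SE = 1/√(n·2f(1−f)) on the SD scale, and
  sampling noise is drawn jointly with correlation equal to the LD
  matrix. Joint effects are calibrated through R⁻¹ so the *marginal*
  z-scores hit their targets: HMGCR z ∈ {6.3, 9.0, 12.0, 14.5, 16.2}
  (F ≈ 40–262, together ≈ 0.54% of LDL-C variance) and PCSK9
  z ∈ {5.9, 6.2, 6.4} (F ≈ 35–41). NPC1L1 carries only sub-threshold
  variants, so selection correctly returns nothing for it.
* **Decoys**: per region, in-window variants with |z| targets below
  genome-wide significance, out-of-window variants half of which are
  genuinely significant (so the cis-window filter is load-bearing), and
  a couple of palindromic near-0.5-frequency variants (so strand-
  ambiguity handling is exercised).
* **CAD GWAS**: 29,319 cases / 183,134 controls; per-allele log-odds are
  θ_CAD × the marginal LDL beta with θ_CAD = 0.4155 per SD-higher
  LDL-C, i.e. a protective OR of exp(−0.4155) ≈ 0.66 per SD-lower
  LDL-C; SEs implied by counts and allele frequency.
* **Cohort**: n = 3,443, age ≈ 17.6 (SD 0.8), 51% male, LDL-C mapped to
  mmol/L (mean 1.61, SD 0.355); individuals on lipid-lowering
  medication (1%) have observed LDL multiplied by 0.7 and the /0.7
  correction is applied before standardization. Genotypes come from a
  latent Gaussian-copula threshold model with tetrachoric-style
  calibration so dosage correlations match the LD matrix. Per-allele
  cohort effects are the GWAS effects scaled up (HMGCR ×3.5, PCSK9 ×4):
  the published conditions — every instrument replicating at p < 0.05
  in n ≈ 3,400 — are only attainable if adolescent per-allele effects
  exceed the middle-aged GWAS betas, and reliable replication of the
  full instrument sets is the structurally important condition for
  exercising the pipeline. GWAS-side strength is kept at the printed
  values; Wald/IVW estimands are ratios and unaffected in expectation.
* **Outcomes**: 100 standardized outcomes, 25 cholesterol-related
  efficacy outcomes with causal LDL effects θ ∈ [0.35, 0.85] and 75
  null safety outcomes (the null-safety scenario is the generator's
  default conclusion-state). Residuals load on a cohort-wide latent
  factor (0.3) and, for about half the outcomes, on near-duplicate pair
  factors (pair correlation 0.985), mirroring NMR-panel redundancy;
  with this structure the 100-outcome panel yields ≈ 75 effective tests
  at the 99% criterion.
* **Attrition**: logistic participation on age, sex and an always-
  observed auxiliary correlated with the outcome factor (~75% response);
  non-responders lose the whole outcome panel, responders an additional
  2% of items at random.

What the generator does **not** emulate: genome-wide variant panels,
haplotype phasing or imputation error, non-Gaussian outcome
distributions, genotype-covariate interactions, population
stratification beyond independent PCs, and medication use correlated
with lipid levels. Passing tests therefore demonstrate correctness of
the estimators and filters under the assumed data-generating structure,
not robustness to violations of it.

## Problem sizes used in the shipped checks

The test suite and the acceptance report scale simulations to what the
statistics require: estimator oracles use 100 random problems at k ≤ 10;
parameter recovery uses 200 cohort-scale replicates (n = 3,443, five
instruments, F > 30) and 1,000 summary-statistic replicates for interval
coverage; family-wise error uses 100 seeded full-cohort runs;
attrition-correction bias comparison uses 200 replicates at n = 6,000
with m = 5; the acceptance report runs the full pipeline with m = 25
imputations (the analysis default is m = 50; pooled estimates are
insensitive to m beyond ~20 and the report documents its choice).

## Known limitations

* First-order Wald SEs understate nothing in the strong-instrument
  regime enforced here but are not valid at F near unity.
* The PCA multiplicity correction assumes the pairwise-complete
  correlation matrix estimates the responder-population correlation;
  severe differential missingness across outcomes could distort n_eff.
* IPW with truncated weights is slightly biased under very strong
  selection (by design, in exchange for variance).
* Harmonization resolves strand by allele complement and frequency
  only; indels and multi-allelic sites are out of scope.
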