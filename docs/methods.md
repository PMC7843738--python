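# Methods

## The problem

A GWAS consortium publishes, per variant, the *marginal* association of a
trait with genotype dosage: effect estimate β̂, its standard error, the
effect-allele frequency and sample counts. Analysts often need the
*conditional* effect — the variant's effect on an outcome Y₁ adjusted for a
second, possibly heritable trait Y₂ (fasting insulin adjusted for BMI, atrial
fibrillation adjusted for height, …) — but rerunning every cohort's GWAS with
the extra covariate is slow and individual-level data usually cannot be
shared. `condgwas` estimates the adjusted effect directly from the published
summary statistics plus a single extra ingredient: an estimate of the
outcome–covariate regression coefficient γₘ.

## The estimator

Write the three regressions (intercepts implicit; identity link for a
continuous trait, logit for a binary one):

* marginal models: E[Yᵢ] ~ X βᵢ for i = 1, 2;
* relationship model: E[Y₁] ~ Y₂ γₘ;
* adjusted model: E[Y₁] ~ X β + Y₂ γ.

For continuous traits and centered data, the adjusted OLS solution is exact
block algebra on scalar cross-products:

    (β̂, γ̂)ᵀ = V⁻¹ D (β̂₁, γ̂ₘ)ᵀ,
    V = [[XᵀX, XᵀY₂], [XᵀY₂, Y₂ᵀY₂]],   D = diag(XᵀX, Y₂ᵀY₂),

because XᵀY₁ = XᵀX·β̂₁ and Y₂ᵀY₁ = Y₂ᵀY₂·γ̂ₘ. Every entry of V is
reconstructible from summary statistics:

* XᵀX ≈ 2n·MAF·(1−MAF) (genotype variance under Hardy–Weinberg equilibrium);
* XᵀY₂ = XᵀX·β̂₂ for a continuous covariate;
* YᵀY = (n−1)·XᵀX·SE(β̂)² + β̂²·XᵀX for a continuous trait. The first term is
  the marginal model's residual sum of squares via the (n−1) residual-variance
  identity; the second adds back the fitted sum of squares so that the total
  centered sum of squares is recovered (at typical GWAS R² the correction is
  ~2% and the (n−1)-vs-(n−2) divisor choice is O(1/n));
* for a binary trait coded 0/1 with n₁ cases: YᵀY = n₁(1 − n₁/n) exactly, and
  XᵀY = n₁(P₁₁+2P₂₁) − n₁[n₀(P₁₀+2P₂₀) + n₁(P₁₁+2P₂₁)]/n from the genotype
  frequencies Pᵢⱼ stratified by case status.

When stratified genotype frequencies are not published they are recovered
from (MAF, β̂₂, n₀, n₁) as the unique pair of stratum allele frequencies
(p₀, p₁) with Hardy–Weinberg proportions within each stratum, per-allele odds
ratio exp(β̂₂) between strata, and pooled frequency equal to MAF; the pooled
constraint is monotone in p₀, so a bracketing root find (brentq, xtol 1e-14)
is guaranteed to converge. A head-to-head comparison in the simulation
harness showed this reconstruction — not the empirically tabulated
frequencies — reproduces the published benchmark's "proposed method" column,
so it is the harness default; observed frequencies override it when supplied.

### Variances

Continuous outcome (exact OLS algebra given the cross-products):

    var(β̂, γ̂) = V⁻¹ · (Y₁ᵀY₁ − β̂·XᵀY₁ − γ̂·Y₂ᵀY₁) / (n − 2),

with Y₂ᵀY₁ = γ̂ₘ·Y₂ᵀY₂. With m covariates the divisor generalizes to
n − m − 1 (the centered design has m+1 columns).

Binary outcome: the same block formula is applied to the logistic β̂₁ and γ̂ₘ
as a heuristic (the first-moment identity behind it is no longer exact), and
the variance follows the sandwich

    var(B̂) = V⁻¹ D Σ D V⁻¹,   Σ = cov(β̂₁, γ̂ₘ).

The off-diagonal of Σ is not published; because score and Wald tests are
asymptotically equivalent in logistic regression, corr(β̂₁, γ̂ₘ) is replaced
by the correlation of the OLS surrogates, a closed-form ratio of the
reconstructed cross-products (numerator var(Y₁)·XᵀY₂/(XᵀX·Y₂ᵀY₂);
denominator the product of the two marginal OLS standard errors), clipped to
[−1, 1], then rescaled by the actual logistic standard errors. The one
cross-product this needs that summary statistics cannot give, Y₁ᵀY₂, comes
from the covariate means among outcome cases and controls:
Y₁ᵀY₂ = n₁(1 − n₁/n)[Mean(Y₂|Y₁=1) − Mean(Y₂|Y₁=0)]. If those means are
unavailable and the relationship was estimated on the full sample, a damped
fallback Y₁ᵀY₂ ≈ γ̂ₘ·p̄(1−p̄)·Y₂ᵀY₂ (p̄ the case fraction) is used and
flagged; otherwise the variant errors out rather than guess.

Tests are Wald: z = β̂/SE(β̂) against the standard normal. GWAS sample sizes
make the normal reference indistinguishable from t; for very small n a t
reference would be slightly more conservative.

## The relationship coefficient γₘ

Three provenances, mirroring what a consortium analyst can actually obtain:
`full` (fitted on the complete phenotype sample), `subset` (a random
subsample — default 20%, i.e. 200 of 1000 in the simulation), and
`literature` (a published point estimate; if its variance is not reported it
defaults to (0.1·γₘ)² with a warning — the adjusted SE is dominated by other
terms in typical applications, but the default is loud on purpose). For
several covariates the *multivariable* relationship fit is used, not pairwise
marginal slopes: the block system needs joint cross-products, and marginal
slopes would double-count variance shared between covariates.

## Harmonization and the allele-frequency filter

Outcome and covariate records are matched on variant id and expressed on a
common effect allele (swapped alleles negate β and reflect EAF; strand flips
are not attempted and palindromic A/T and C/G variants are flagged, not
auto-resolved — flipping them silently is unsafe). Because the two GWAS may
come from different consortia, a variant's allele frequency can disagree
grossly between them, which corrupts every reconstructed cross-product; a
two-proportion z-test on allele counts (2n·EAF) removes variants with
p < α / (number tested). Mean- and min-frequency compromises are exposed as
`freq_strategy` options but filtering is the recommended remedy.

## The synthetic world

All generators default to the stated benchmark world: 1000 replicates of
n = 1000 individuals; genotypes Binomial(2, MAF) with MAF ∈ {2, 5, 10, 25}%;
the variant explains 4% of the covariate variance and 2% of the outcome
variance; the covariate explains 20% of the outcome variance. Because X and
Y₂ are correlated, "2% by X and 20% by Y₂" is ambiguous; the implemented
convention sets β = √(0.02/var(X)), γ = √(0.20/var(Y₂)) with residual
variance 1 − 0.02 − 0.20 — the convention whose implied coefficients
(0.714/0.459/0.333/0.231 across the MAF grid) match the gold-standard means
it is benchmarked against.

Binary traits use a latent-threshold rule with genotype-specific *case
probabilities* 0.1/0.2/0.4 for dosage 0/1/2. (Read as "latent exceeds the
threshold" the rule yields negative genetic effects; the probability reading
is the one consistent with the positive benchmark effects, and reproduces
them to ~0.005.) A binary outcome with a continuous covariate additionally
requires Y₂ above its 20th percentile.

Two binary traits: the covariate comes first from the threshold rule, the
continuous adjusted-model trait is built from it, and the outcome is
I(expit(0.8·X + 2.0·Y₁ᶜᵒⁿᵗ) + N(0, 0.1²) ≥ Q₈₀) — exactly 20% outcome cases
per replicate. The source text for this scenario is internally inconsistent
(it uses a variable before defining it); among ~10 candidate readings this is
the only one that reproduces all four benchmark SE columns
(0.360/0.235/0.179/0.135 vs published 0.364/0.234/0.172/0.133), the positive
signs, and the documented ~10% low-MAF approximation bias (13% at MAF 2%, 3%
at 25%). Its replicate-mean *effects* at low MAF are nonetheless larger than
the published ones (1.75 vs 0.87 at MAF 2%); no textually consistent reading
matched those means, and the corresponding absolute-value acceptance test is
deliberately left failing rather than tuned.

Type I error uses two nulls: s1 (variant associated with neither trait) and
s2 (variant associated with the covariate only, so the marginal outcome
association is pure confounding). Power keeps the variant independent of the
covariate, with the variant explaining 1% (continuous outcome) or 8%
(binary, on the liability scale, dichotomized at its 80th percentile) of the
outcome variance and the covariate share swept over {5, 10, 20, 40}%. Power
curves share common random numbers across the sweep, so the ordering of
empirical power across covariate shares is free of between-cell Monte-Carlo
noise.

What the generators do *not* emulate: linkage disequilibrium between
variants, relatedness/family structure, covariate measurement error,
imputation dosage uncertainty, and trait transformations (the method is
known to degrade under inverse-normal transformation of the outcome — rerun
individual-level analyses in that case). A green simulation therefore
establishes correctness of the estimator's algebra and its calibration in an
idealized cohort, not robustness to those real-data features.

## Numerical choices

* Near-singularity: V is rejected when its eigenvalue ratio falls below
  1e-12 (collinearity error naming the variant).
* Nonpositive reconstructed residual sums of squares raise an error; in the
  simulation harness such replicates are excluded and counted, and more than
  1% exclusions aborts the run.
* Σ failing positive semidefiniteness has its off-diagonal clipped to the
  boundary with a warning.
* Logistic fits: IRLS from zero with step-halving (tolerated likelihood
  decrease 1e-10), convergence when the step's max norm < 1e-10, max 50
  iterations; separation is reported as an error, not a huge coefficient.
* Unequal sample sizes between the two GWAS: covariate cross-products are
  rescaled to the outcome sample size through per-individual variances; the
  rescaling is a no-op when sizes agree.

## Known limitations

* Binary-outcome results are a heuristic approximation; with both traits
  binary and MAF ≤ 5% the adjusted effect is biased downward by roughly 10%
  relative to the individual-level fit, and the sandwich variance is mildly
  conservative under the null (empirical type I error ~0.026 at α = 0.05 in
  the two-binary null — deflation, consistent with the method's reported
  behavior; it never inflates).
* Adjusting for a heritable covariate can itself bias the genetic effect
  (collider structure); report adjusted and unadjusted results side by side.
* Single-variant conditioning only: no LD-aware multi-SNP adjustment, no
  meta-analysis across cohorts, no genome-build liftover.
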