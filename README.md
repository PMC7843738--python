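# condgwas

Approximate conditional phenotype analysis from GWAS summary statistics.

## The problem

A genome-wide association study reports each variant's *marginal* effect on a
trait. When a second trait confounds the association — BMI for fasting
insulin, height for atrial fibrillation — the analysis of record is the
*conditional* model, outcome ~ variant + covariate, which normally requires
rerunning every contributing cohort on individual-level data. `condgwas`
estimates that adjusted effect using only what consortia already publish:
per-variant beta, standard error, effect-allele frequency and sample counts
(plus case/control counts for binary traits), together with one scalar an
analyst can always obtain — the outcome–covariate regression coefficient γₘ,
fitted on a phenotype subset or taken from the literature. Both the outcome
and the covariate may be continuous or binary, and several covariates can be
adjusted for jointly.

## The core computation

For centered data the adjusted ordinary-least-squares solution is block
algebra on scalar cross-products:

    (β̂, γ̂)ᵀ = V⁻¹ D (β̂₁, γ̂ₘ)ᵀ,   V = [[XᵀX, XᵀY₂], [XᵀY₂, Y₂ᵀY₂]],
                                    D = diag(XᵀX, Y₂ᵀY₂),

where β̂₁ is the published marginal effect. Every entry of V is
reconstructed from summary statistics: XᵀX ≈ 2n·MAF(1−MAF) under
Hardy–Weinberg equilibrium; XᵀY = XᵀX·β̂ and YᵀY from the standard-error
identity for continuous traits; YᵀY = n₁(1−n₁/n) exactly and XᵀY from
case/control-stratified genotype frequencies (recovered from MAF, the
log-odds ratio and the counts when unpublished) for binary traits. Variances
are exact OLS algebra for continuous outcomes and a sandwich
V⁻¹DΣDV⁻¹ for binary outcomes, with the correlation between the marginal
estimates approximated by its OLS surrogate. See `docs/methods.md` for the
full derivations, conventions and limitations.

With exact cross-products and both traits continuous the result *equals* the
individual-level fit to machine precision; the binary-outcome cases are
heuristic and validated by simulation (known caveat: ~10% downward bias when
both traits are binary and MAF ≤ 5%).

## Worked example

```python
import numpy as np
from condgwas import (PhenotypeTable, approx_conditional, estimate_gamma_m,
                      oracle, simulate)
from condgwas.simulate import SimConfig

rng = np.random.default_rng(1)
rep = simulate.gen_cc(1000, 0.25, SimConfig(), rng)   # one synthetic cohort
out_rec, cov_rec, extras = simulate.summarize_to_sumstats(rep)
rel = estimate_gamma_m(PhenotypeTable(rep.y1, rep.y2))
res = approx_conditional(out_rec, cov_rec, rel, extras=extras)
fit = oracle.fit_ols(rep.y1, np.column_stack([np.ones(1000), rep.x, rep.y2]))

print(f"marginal beta: {out_rec.beta:.3f} (SE {out_rec.se:.3f})")
print(f"adjusted beta (summary stats): {res.beta_adj:.3f} (SE {res.se_adj:.3f}), p = {res.p:.2e}")
print(f"adjusted beta (individual-level): {fit.coef[1]:.3f} (SE {fit.se[1]:.3f})")
```

prints

```
marginal beta: 0.391 (SE 0.048)
adjusted beta (summary stats): 0.235 (SE 0.044), p = 1.20e-07
adjusted beta (individual-level): 0.235 (SE 0.044)
```

The marginal effect (0.391) is inflated by the covariate path; the
summary-statistics adjustment recovers the individual-level conditional
estimate (0.235 vs 0.235, truth 0.231) without touching genotype data.

A command-line interface wraps the table-level workflow:

```
condgwas run --outcome outcome.tsv --covariate covariate.tsv \
    --gamma-m 0.45 --gamma-m-var 0.001 --out adjusted.tsv
condgwas simulate --scenario cc --maf 0.25 --reps 1000 --seed 7
```

`condgwas run` harmonizes alleles between the two files, drops variants whose
allele frequencies differ significantly between datasets (Bonferroni-corrected
two-proportion test), and appends `beta_adj`, `se_adj`, `z_adj`, `p_adj`
columns.

## Validation harness

`condgwas.simulate` and `condgwas.evaluate` implement the full benchmark:
four generative scenarios (every continuous/binary combination of outcome and
covariate), three γₘ provenances (full sample, 20% subset, literature-style
±20% perturbation), type I error under two null configurations, and power
with the variant independent of the covariate. `tests/test_acceptance.py`
asserts the replicate-mean estimates, calibration and power ordering.

`scripts/acceptance.py` re-runs the pipeline from scratch on a reduced grid —
data generation, gold-standard fits, summary-statistic reduction, approximate
conditional estimation — printing per-cell gold vs approximate estimates,
empirical type I error and the power sweep:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
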