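"""Replicate grids: benchmark the approximation against individual-level fits.

For every replicate the gold standard is the adjusted model fitted on the
individual-level data (OLS for a continuous outcome, logistic regression for a
binary one); the approximation sees only the derived summary statistics plus
one of three relationship strategies:

* ``full``       — relationship fitted on the replicate's complete sample;
* ``subset``     — fitted on a random 20% subsample;
* ``literature`` — a value drawn uniformly within ±20% of the full-data
  estimate, mimicking a published report.

Replicate-averaged effect estimates, standard errors and rejection rates are
aggregated into tidy tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import oracle, simulate
from .conditional import ConditionalExtras, approx_conditional
from .errors import CondgwasError
from .relationship import PhenotypeTable, estimate_gamma_m, literature_gamma_m, subset_gamma_m
from .simulate import SimConfig, SimReplicate, SimScenario

__all__ = [
    "STRATEGIES",
    "replicate_estimates",
    "run_grid",
    "run_table1",
    "run_type1",
    "run_power",
    "compare_estimates",
    "ComparisonSummary",
    "genomic_lambda",
]

STRATEGIES = ("full", "subset", "literature")

_GENERATORS = {
    "cc": simulate.gen_cc,
    "cb": simulate.gen_cb,
    "bc": simulate.gen_bc,
    "bb": simulate.gen_bb,
}

#: hard cap on the share of replicates an estimator error may remove
MAX_EXCLUSION_FRACTION = 0.01


def _gold_fit(rep: SimReplicate) -> tuple[float, float, float]:
    """Adjusted-model fit on individual-level data: (beta, se, p)."""
    n = len(rep.x)
    design = np.column_stack([np.ones(n), rep.x, rep.y2])
    if rep.outcome_type == "continuous":
        fit = oracle.fit_ols(rep.y1, design)
    else:
        fit = oracle.fit_logistic(rep.y1, design)
    z = fit.coef[1] / fit.se[1]
    return float(fit.coef[1]), float(fit.se[1]), float(2 * stats.norm.sf(abs(z)))


def _relationship(rep: SimReplicate, strategy: str, rng: np.random.Generator, subset_fraction: float = 0.2, literature_band: float = 0.2):
    link = "logit" if rep.outcome_type == "binary" else "identity"
    table = PhenotypeTable(rep.y1, rep.y2)
    if strategy == "subset":
        seed = int(rng.integers(0, 2**31 - 1))
        return subset_gamma_m(table, subset_fraction, seed=seed, link=link)
    full = estimate_gamma_m(table, link=link)
    if strategy == "full":
        return full
    if strategy == "literature":
        lo, hi = sorted(
            ((1 - literature_band) * full.gamma_m, (1 + literature_band) * full.gamma_m)
        )
        value = float(rng.uniform(lo, hi))
        # the published-report mimic carries a point estimate only; use the
        # default coefficient-of-variation policy without the per-call warning
        variance = max((0.1 * value) ** 2, 1e-12)
        return literature_gamma_m(value, variance, link=link)
    raise ValueError(f"unknown strategy {strategy}")


def replicate_estimates(
    rep: SimReplicate,
    strategies: tuple[str, ...],
    rng: np.random.Generator,
    subset_fraction: float = 0.2,
    literature_band: float = 0.2,
    use_observed_freqs: bool = False,
) -> dict[str, tuple[float, float, float]]:
    """Gold-standard and approximate (beta, se, p) for one replicate.

    By default the approximation sees only what a consortium publishes:
    marginal summary statistics plus, for a binary outcome, the covariate
    means among cases and controls — genotype frequencies stratified by case
    status are *reconstructed* from MAF, the marginal log-odds ratio and the
    case/control counts.  ``use_observed_freqs=True`` hands the empirically
    tabulated stratified frequencies to the estimator instead.
    """
    out: dict[str, tuple[float, float, float]] = {"gold": _gold_fit(rep)}
    out_rec, cov_rec, extras = simulate.summarize_to_sumstats(rep)
    if not use_observed_freqs:
        extras = ConditionalExtras(
            mean_y2_cases=extras.mean_y2_cases,
            mean_y2_controls=extras.mean_y2_controls,
        )
    for strategy in strategies:
        rel = _relationship(rep, strategy, rng, subset_fraction, literature_band)
        res = approx_conditional(out_rec, cov_rec, rel, extras=extras)
        out[strategy] = (res.beta_adj, res.se_adj, res.p)
    return out


def run_grid(
    scenario: SimScenario, strategies: tuple[str, ...] = STRATEGIES, alpha: float = 0.05
) -> pd.DataFrame:
    """Run one simulation cell; one aggregated row per estimation route.

    Columns: mean and SD of the effect estimate, mean standard error,
    rejection rate at ``alpha``, replicate and exclusion counts.  A replicate
    failing inside the estimator is excluded and counted; more than 1%
    exclusions aborts the run.
    """
    gen = _GENERATORS[scenario.scenario]
    rows: dict[str, list[tuple[float, float, float]]] = {
        name: [] for name in ("gold", *strategies)
    }
    excluded = 0
    for i in range(scenario.reps):
        rng = np.random.default_rng((scenario.seed, i))
        rep = gen(scenario.n, scenario.maf, scenario.config, rng)
        try:
            est = replicate_estimates(
                rep, strategies, rng, scenario.subset_fraction, scenario.literature_band
            )
        except CondgwasError:
            excluded += 1
            if excluded > max(1, MAX_EXCLUSION_FRACTION * scenario.reps):
                raise
            continue
        for name, triple in est.items():
            rows[name].append(triple)

    records = []
    for name, triples in rows.items():
        arr = np.asarray(triples)
        records.append(
            dict(
                scenario=scenario.scenario,
                maf=scenario.maf,
                strategy=name,
                mean_beta=arr[:, 0].mean(),
                sd_beta=arr[:, 0].std(ddof=1) if len(triples) > 1 else 0.0,
                mean_se=arr[:, 1].mean(),
                reject_rate=float((arr[:, 2] < alpha).mean()),
                reps=len(triples),
                excluded=excluded,
                seed=scenario.seed,
            )
        )
    return pd.DataFrame(records)


def run_table1(
    scenarios: tuple[str, ...] = ("cc", "cb", "bc", "bb"),
    mafs: tuple[float, ...] = (0.02, 0.05, 0.10, 0.25),
    n: int = 1000,
    reps: int = 1000,
    seed: int = 0,
    strategies: tuple[str, ...] = STRATEGIES,
) -> pd.DataFrame:
    """The full benchmark grid (all trait-type scenarios x all MAFs)."""
    frames = []
    for k, sc in enumerate(scenarios):
        for j, maf in enumerate(mafs):
            cell = SimScenario(
                scenario=sc, maf=maf, n=n, reps=reps, seed=seed + 1000 * k + 100 * j
            )
            frames.append(run_grid(cell, strategies=strategies))
    return pd.concat(frames, ignore_index=True)


def run_type1(
    kinds: tuple[str, ...] = ("cc", "cb", "bc", "bb"),
    null_scenario: str = "s1",
    n: int = 1000,
    reps: int = 1000,
    seed: int = 0,
    strategies: tuple[str, ...] = ("full",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical type I error of gold standard and approximation."""
    records = []
    cfg = SimConfig()
    for k, kind in enumerate(kinds):
        rejections: dict[str, list[float]] = {name: [] for name in ("gold", *strategies)}
        excluded = 0
        for i in range(reps):
            rng = np.random.default_rng((seed, 7000 + k, i))
            rep = simulate.gen_type1(kind, null_scenario, n, 0.25, cfg, rng)
            try:
                est = replicate_estimates(rep, strategies, rng)
            except CondgwasError:
                excluded += 1
                if excluded > max(1, MAX_EXCLUSION_FRACTION * reps):
                    raise
                continue
            for name, (_, _, p) in est.items():
                rejections[name].append(p)
        for name, ps in rejections.items():
            ps_arr = np.asarray(ps)
            records.append(
                dict(
                    scenario=f"type1_{null_scenario}_{kind}",
                    strategy=name,
                    type1=float((ps_arr < alpha).mean()),
                    reps=len(ps),
                    excluded=excluded,
                )
            )
    return pd.DataFrame(records)


def run_power(
    outcome_type: str = "continuous",
    fractions: tuple[float, ...] = (0.05, 0.10, 0.20, 0.40),
    maf: float = 0.25,
    n: int = 1000,
    reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power of the marginal test vs the covariate-adjusted approximation.

    The variant is independent of the covariate.  The covariate fractions
    share common random numbers within a replicate, so the power curve across
    fractions is free of between-cell Monte-Carlo noise.
    """
    marginal_reject = {f: 0 for f in fractions}
    adjusted_reject = {f: 0 for f in fractions}
    gold_reject = {f: 0 for f in fractions}
    counted = {f: 0 for f in fractions}
    for i in range(reps):
        rng = np.random.default_rng((seed, 9000, i))
        x = simulate.gen_genotype(n, maf, rng)
        y2 = rng.normal(0.0, 1.0, n)
        eps = rng.normal(0.0, 1.0, n)
        for frac in fractions:
            rep = simulate.gen_power(
                n, maf, frac, outcome_type, rng, base=(x, y2, eps)
            )
            try:
                est = replicate_estimates(rep, ("full",), rng)
                out_rec, _, _ = simulate.summarize_to_sumstats(rep)
            except CondgwasError:
                continue
            counted[frac] += 1
            z_marg = out_rec.beta / out_rec.se
            if 2 * stats.norm.sf(abs(z_marg)) < alpha:
                marginal_reject[frac] += 1
            if est["full"][2] < alpha:
                adjusted_reject[frac] += 1
            if est["gold"][2] < alpha:
                gold_reject[frac] += 1
    return pd.DataFrame(
        [
            dict(
                outcome_type=outcome_type,
                var_y2_on_y1=f,
                power_marginal=marginal_reject[f] / counted[f],
                power_adjusted=adjusted_reject[f] / counted[f],
                power_gold=gold_reject[f] / counted[f],
                reps=counted[f],
            )
            for f in fractions
        ]
    )


@dataclass(frozen=True)
class ComparisonSummary:
    """Agreement between approximate and gold-standard results."""

    r_beta: float
    r_neglog10p: float
    mean_rel_diff_beta: float


def compare_estimates(
    gold_beta: np.ndarray,
    gold_p: np.ndarray,
    approx_beta: np.ndarray,
    approx_p: np.ndarray,
) -> ComparisonSummary:
    """Pearson correlations of effects and -log10 p, and mean relative effect difference."""
    gold_beta = np.asarray(gold_beta, dtype=float)
    approx_beta = np.asarray(approx_beta, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_beta = float(np.corrcoef(gold_beta, approx_beta)[0, 1])
        r_p = float(
            np.corrcoef(
                -np.log10(np.asarray(gold_p)), -np.log10(np.asarray(approx_p))
            )[0, 1]
        )
    rel = abs(gold_beta.mean() - approx_beta.mean()) / abs(gold_beta.mean())
    return ComparisonSummary(r_beta=r_beta, r_neglog10p=r_p, mean_rel_diff_beta=float(rel))


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square over its null median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
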