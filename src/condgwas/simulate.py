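"""Synthetic individual-level data for validating the conditional estimator.

Four generative scenarios cover the combinations of continuous/binary outcome
(Y1) and adjustment covariate (Y2), plus null (type I error) and power
configurations.  Defaults encode the stated simulation world: n = 1000
individuals per replicate, genotypes drawn Binomial(2, MAF) with MAF in
{0.02, 0.05, 0.10, 0.25}, the variant explaining 4% of the covariate variance
and 2% of the outcome variance, and the covariate explaining 20% of the
outcome variance.

Variance-fraction convention: because the variant and the covariate are
correlated in the adjusted model, "2% explained by X and 20% by Y2" is
ambiguous; here the coefficients are set as beta = sqrt(0.02 / var(X)) and
gamma = sqrt(0.20 / var(Y2)) with the residual making the orthogonal variance
budget sum to one.  This is the convention whose implied coefficients
(0.714 / 0.459 / 0.333 / 0.231 at the four MAFs) match the gold-standard
means the estimator is benchmarked against.

Binary traits are generated by a latent-threshold rule with genotype-specific
case probabilities 0.1 / 0.2 / 0.4 for genotype 0 / 1 / 2 (a uniform(0,1)
latent variable below the threshold); for a binary outcome with a continuous
covariate the outcome additionally requires the covariate to exceed its 20th
percentile.
For two binary traits, the binary covariate comes first from the threshold
rule, a continuous trait is built from it per the adjusted model, and the
outcome is the score X*0.8 + (continuous trait)*2.0 squashed through the
inverse logit, perturbed with N(0, 0.1^2) noise, and dichotomized at its 80th
empirical percentile (so the outcome has exactly 20% cases per replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import oracle
from .conditional import ConditionalExtras
from .errors import DomainError
from .reconstruct import StratifiedGenoFreqs
from .summary_io import SummaryRecord

__all__ = [
    "SimConfig",
    "SimScenario",
    "SimReplicate",
    "GENO_THRESHOLDS",
    "gen_genotype",
    "gen_binary_outcome",
    "gen_cc",
    "gen_cb",
    "gen_bc",
    "gen_bb",
    "gen_type1",
    "gen_power",
    "summarize_to_sumstats",
]

#: latent-threshold per genotype for binary trait generation
GENO_THRESHOLDS = (0.1, 0.2, 0.4)
#: slope of genotype and of the binary outcome in the two-binary-trait score
BB_BETA2_STAR = 0.8
BB_GAMMA_STAR = 2.0
BB_NOISE_SD = 0.1
BB_CASE_QUANTILE = 0.8
#: percentile of the covariate required for a binary outcome (bc scenario)
Y2_CONDITION_QUANTILE = 0.2


@dataclass(frozen=True)
class SimConfig:
    """Variance-fraction configuration of the generative model."""

    var_x_on_y2: float = 0.04
    var_x_on_y1: float = 0.02
    var_y2_on_y1: float = 0.20

    def __post_init__(self) -> None:
        for f in (self.var_x_on_y2, self.var_x_on_y1, self.var_y2_on_y1):
            if not 0.0 <= f < 1.0:
                raise DomainError("variance fractions must lie in [0, 1)")
        if self.var_x_on_y1 + self.var_y2_on_y1 >= 1.0:
            raise DomainError("outcome variance budget exceeds 1")


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation grid."""

    scenario: str  # cc | cb | bc | bb | type1_s1 | type1_s2 | power
    maf: float = 0.25
    n: int = 1000
    reps: int = 1000
    config: SimConfig = field(default_factory=SimConfig)
    gamma_strategy: str = "full"  # full | subset | literature
    subset_fraction: float = 0.2
    literature_band: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 0.5:
            raise DomainError("maf must lie in (0, 0.5)")


@dataclass
class SimReplicate:
    """One simulated dataset with its generating truth."""

    x: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    outcome_type: str
    covariate_type: str
    beta_true: float | None = None
    gamma_true: float | None = None


def gen_genotype(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. Binomial(2, maf) genotype dosages."""
    if not 0.0 <= maf <= 0.5:
        raise DomainError("maf must lie in [0, 0.5]")
    return rng.binomial(2, maf, size=n)


def gen_binary_outcome(
    x: np.ndarray,
    rng: np.random.Generator,
    y2: np.ndarray | None = None,
    thresholds: tuple[float, float, float] = GENO_THRESHOLDS,
    y2_quantile: float = Y2_CONDITION_QUANTILE,
) -> np.ndarray:
    """Latent-threshold binary trait, optionally conditioned on the covariate.

    The trait is 1 when a uniform(0,1) latent variable falls below the
    genotype-specific threshold (so the threshold is the genotype-specific
    case probability, increasing in dosage) and, when ``y2`` is given, the
    covariate exceeds its ``y2_quantile`` percentile.
    """
    thr = np.asarray(thresholds, dtype=float)[x]
    y = rng.uniform(size=len(x)) < thr
    if y2 is not None:
        y &= y2 > np.quantile(y2, y2_quantile)
    return y.astype(float)


def _cc_coefs(maf: float, cfg: SimConfig, var_y2: float = 1.0):
    var_x = 2.0 * maf * (1.0 - maf)
    beta = np.sqrt(cfg.var_x_on_y1 / var_x)
    gamma = np.sqrt(cfg.var_y2_on_y1 / var_y2)
    resid_sd = np.sqrt(1.0 - cfg.var_x_on_y1 - cfg.var_y2_on_y1)
    return beta, gamma, resid_sd


def gen_cc(
    n: int, maf: float, cfg: SimConfig, rng: np.random.Generator
) -> SimReplicate:
    """Continuous outcome, continuous covariate."""
    x = gen_genotype(n, maf, rng)
    var_x = 2.0 * maf * (1.0 - maf)
    beta2 = np.sqrt(cfg.var_x_on_y2 / var_x)
    y2 = x * beta2 + rng.normal(0.0, np.sqrt(1.0 - cfg.var_x_on_y2), n)
    beta, gamma, resid_sd = _cc_coefs(maf, cfg)
    y1 = x * beta + y2 * gamma + rng.normal(0.0, resid_sd, n)
    return SimReplicate(x, y1, y2, "continuous", "continuous", beta, gamma)


def binary_trait_prevalence(
    maf: float, thresholds: tuple[float, float, float] = GENO_THRESHOLDS
) -> float:
    """P(trait = 1) under HWE for the latent-threshold rule."""
    probs = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    return float(probs @ np.asarray(thresholds))


def gen_cb(
    n: int, maf: float, cfg: SimConfig, rng: np.random.Generator
) -> SimReplicate:
    """Continuous outcome, binary covariate (latent-threshold rule)."""
    x = gen_genotype(n, maf, rng)
    y2 = gen_binary_outcome(x, rng)
    p = binary_trait_prevalence(maf)
    beta, gamma, resid_sd = _cc_coefs(maf, cfg, var_y2=p * (1.0 - p))
    y1 = x * beta + y2 * gamma + rng.normal(0.0, resid_sd, n)
    return SimReplicate(x, y1, y2, "continuous", "binary", beta, gamma)


def gen_bc(
    n: int, maf: float, cfg: SimConfig, rng: np.random.Generator
) -> SimReplicate:
    """Binary outcome, continuous covariate."""
    x = gen_genotype(n, maf, rng)
    var_x = 2.0 * maf * (1.0 - maf)
    beta2 = np.sqrt(cfg.var_x_on_y2 / var_x)
    y2 = x * beta2 + rng.normal(0.0, np.sqrt(1.0 - cfg.var_x_on_y2), n)
    y1 = gen_binary_outcome(x, rng, y2=y2)
    return SimReplicate(x, y1, y2, "binary", "continuous")


def gen_bb(
    n: int, maf: float, cfg: SimConfig, rng: np.random.Generator
) -> SimReplicate:
    """Binary outcome and binary covariate.

    The covariate comes first from the latent-threshold rule, exactly as in
    the continuous-outcome/binary-covariate scenario, together with the
    continuous trait the adjusted model implies.  The binary outcome is the
    score X*0.8 + (continuous trait)*2.0 squashed through the inverse logit,
    noised with N(0, 0.1^2), and dichotomized at its empirical 80th
    percentile (exactly 20% outcome cases per replicate).
    """
    x = gen_genotype(n, maf, rng)
    y2 = gen_binary_outcome(x, rng)
    p = binary_trait_prevalence(maf)
    beta, gamma, resid_sd = _cc_coefs(maf, cfg, var_y2=p * (1.0 - p))
    y1_cont = x * beta + y2 * gamma + rng.normal(0.0, resid_sd, n)
    score = x * BB_BETA2_STAR + y1_cont * BB_GAMMA_STAR
    tilde = 1.0 / (1.0 + np.exp(-score)) + rng.normal(0.0, BB_NOISE_SD, n)
    y1 = (tilde >= np.quantile(tilde, BB_CASE_QUANTILE)).astype(float)
    return SimReplicate(x, y1, y2, "binary", "binary")


def gen_type1(
    kind: str,
    scenario: str,
    n: int,
    maf: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> SimReplicate:
    """Null data for type I error evaluation.

    ``scenario='s1'``: the variant is associated with neither trait.
    ``scenario='s2'``: the variant is associated with the covariate only
    (marginal outcome association flows entirely through the covariate, so
    the conditional effect is null).
    """
    if scenario not in ("s1", "s2"):
        raise DomainError(f"unknown type I scenario {scenario}")
    x = gen_genotype(n, maf, rng)
    var_x = 2.0 * maf * (1.0 - maf)
    x_on_y2 = scenario == "s2"
    flat = (GENO_THRESHOLDS[0],) * 3  # genotype-independent thresholds

    if kind == "cc":
        beta2 = np.sqrt(cfg.var_x_on_y2 / var_x) if x_on_y2 else 0.0
        y2 = x * beta2 + rng.normal(0.0, np.sqrt(1.0 - cfg.var_x_on_y2), n)
        gamma = np.sqrt(cfg.var_y2_on_y1)
        y1 = y2 * gamma + rng.normal(0.0, np.sqrt(1.0 - cfg.var_y2_on_y1), n)
        return SimReplicate(x, y1, y2, "continuous", "continuous", 0.0, gamma)
    if kind == "cb":
        y2 = gen_binary_outcome(x, rng, thresholds=GENO_THRESHOLDS if x_on_y2 else flat)
        p = (
            binary_trait_prevalence(maf)
            if x_on_y2
            else 1.0 - GENO_THRESHOLDS[0]
        )
        gamma = np.sqrt(cfg.var_y2_on_y1 / (p * (1.0 - p)))
        y1 = y2 * gamma + rng.normal(0.0, np.sqrt(1.0 - cfg.var_y2_on_y1), n)
        return SimReplicate(x, y1, y2, "continuous", "binary", 0.0, gamma)
    if kind == "bc":
        beta2 = np.sqrt(cfg.var_x_on_y2 / var_x) if x_on_y2 else 0.0
        y2 = x * beta2 + rng.normal(0.0, np.sqrt(1.0 - cfg.var_x_on_y2), n)
        y1 = gen_binary_outcome(x, rng, y2=y2, thresholds=flat)
        return SimReplicate(x, y1, y2, "binary", "continuous", 0.0, None)
    if kind == "bb":
        # the variant must not reach the outcome except through the covariate
        y2 = gen_binary_outcome(x, rng, thresholds=GENO_THRESHOLDS if x_on_y2 else flat)
        p = (
            binary_trait_prevalence(maf) if x_on_y2 else GENO_THRESHOLDS[0]
        )
        gamma = np.sqrt(cfg.var_y2_on_y1 / (p * (1.0 - p)))
        y1_cont = y2 * gamma + rng.normal(0.0, np.sqrt(1.0 - cfg.var_y2_on_y1), n)
        score = y1_cont * BB_GAMMA_STAR
        tilde = 1.0 / (1.0 + np.exp(-score)) + rng.normal(0.0, BB_NOISE_SD, n)
        y1 = (tilde >= np.quantile(tilde, BB_CASE_QUANTILE)).astype(float)
        return SimReplicate(x, y1, y2, "binary", "binary", 0.0, None)
    raise DomainError(f"unknown scenario kind {kind}")


#: genetic variance fraction of the outcome in power simulations
POWER_GENETIC_FRACTION = {"continuous": 0.01, "binary": 0.08}


def gen_power(
    n: int,
    maf: float,
    var_y2_on_y1: float,
    outcome_type: str,
    rng: np.random.Generator,
    base: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> SimReplicate:
    """Power configuration: the variant is independent of the covariate.

    The variant explains 1% (continuous outcome) or 8% (binary outcome, on the
    liability) of the outcome variance; the covariate explains
    ``var_y2_on_y1``.  A binary outcome dichotomizes the liability at its 80th
    percentile.  ``base`` may supply pre-drawn (x, y2, standard-normal noise)
    so that power curves across covariate fractions share common random
    numbers.
    """
    g = POWER_GENETIC_FRACTION[outcome_type]
    if var_y2_on_y1 + g >= 1.0:
        raise DomainError("variance budget exceeds 1")
    if base is None:
        x = gen_genotype(n, maf, rng)
        y2 = rng.normal(0.0, 1.0, n)
        eps = rng.normal(0.0, 1.0, n)
    else:
        x, y2, eps = base
    var_x = 2.0 * maf * (1.0 - maf)
    beta = np.sqrt(g / var_x)
    gamma = np.sqrt(var_y2_on_y1)
    liability = x * beta + y2 * gamma + eps * np.sqrt(1.0 - g - var_y2_on_y1)
    if outcome_type == "continuous":
        y1 = liability
    else:
        y1 = (liability >= np.quantile(liability, 0.8)).astype(float)
    return SimReplicate(x, y1, y2, outcome_type, "continuous", beta, gamma)


def _stratified_freqs(x: np.ndarray, status: np.ndarray) -> StratifiedGenoFreqs:
    table = np.empty((3, 2))
    for j in (0, 1):
        sel = x[status == j]
        counts = np.bincount(sel.astype(int), minlength=3)[:3]
        table[:, j] = counts / counts.sum()
    return StratifiedGenoFreqs(table)


def summarize_to_sumstats(
    rep: SimReplicate, variant_id: str = "sim"
) -> tuple[SummaryRecord, SummaryRecord, ConditionalExtras]:
    """Reduce a replicate to the summary statistics a consortium would publish.

    Fits the two marginal models, records beta/SE/EAF/sample counts, and
    collects the cohort-level extras (stratified genotype frequencies for
    binary traits, covariate means among outcome cases/controls for binary
    outcomes) directly from the data.
    """
    n = len(rep.x)
    design = np.column_stack([np.ones(n), rep.x])
    eaf = float(rep.x.mean() / 2.0)

    def marginal(y: np.ndarray, trait_type: str) -> SummaryRecord:
        if trait_type == "continuous":
            fit = oracle.fit_ols(y, design)
            cases = controls = None
        else:
            fit = oracle.fit_logistic(y, design)
            cases, controls = int(y.sum()), int(n - y.sum())
        return SummaryRecord(
            variant_id=variant_id,
            effect_allele="A",
            other_allele="G",
            eaf=eaf,
            beta=float(fit.coef[1]),
            se=float(fit.se[1]),
            n=n,
            trait_type=trait_type,
            n_cases=cases,
            n_controls=controls,
        )

    out_rec = marginal(rep.y1, rep.outcome_type)
    cov_rec = marginal(rep.y2, rep.covariate_type)

    freqs_cov = (
        _stratified_freqs(rep.x, rep.y2) if rep.covariate_type == "binary" else None
    )
    freqs_out = (
        _stratified_freqs(rep.x, rep.y1) if rep.outcome_type == "binary" else None
    )
    mean_cases = mean_controls = None
    if rep.outcome_type == "binary":
        mean_cases = float(rep.y2[rep.y1 == 1].mean())
        mean_controls = float(rep.y2[rep.y1 == 0].mean())
    extras = ConditionalExtras(
        geno_freqs_covariate=freqs_cov,
        geno_freqs_outcome=freqs_out,
        mean_y2_cases=mean_cases,
        mean_y2_controls=mean_controls,
    )
    return out_rec, cov_rec, extras
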