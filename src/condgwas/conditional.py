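"""Approximate conditional association analysis from summary statistics.

The adjusted model regresses the outcome on the genetic variant *and* an
adjustment covariate.  On individual-level centered data the OLS solution is
pure block algebra on scalar cross-products:

    B = V^{-1} D (beta1, gamma_m)^T,
    V = [[X'X, X'Y2], [X'Y2, Y2'Y2]],   D = diag(X'X, Y2'Y2),

where beta1 is the marginal variant effect on the outcome and gamma_m the
outcome-covariate regression slope.  Every entry of V and D is reconstructible
from published summary statistics (see :mod:`condgwas.reconstruct`), so the
adjusted effect needs no individual-level genotype data.  For continuous
outcomes the variance is the usual OLS form; for binary outcomes the same
block algebra is applied to logistic coefficients as a heuristic and the
variance follows a sandwich built from the marginal sampling variances, with
the correlation between the marginal estimates approximated by its OLS
surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, DomainError, InputError
from .reconstruct import (
    CrossProducts,
    StratifiedGenoFreqs,
    estimate_stratified_geno_freqs,
    xtx_from_maf,
    xty2_binary,
    xty_from_beta,
    y1ty2_binary_cont,
    y2ty2_binary,
    yty_from_se,
)
from .relationship import RelationshipMatrix, TraitRelationship
from .summary_io import HarmonizedPair, SummaryRecord, harmonize

__all__ = [
    "ConditionalResult",
    "ConditionalExtras",
    "solve_block",
    "var_block_continuous",
    "cov_beta1_gamma_m",
    "var_block_binary",
    "build_cross_products",
    "approx_conditional",
    "conditional_multi",
    "adjust_table",
]

#: reciprocal condition number below which V is treated as singular
RCOND_THRESHOLD = 1e-12


@dataclass(frozen=True)
class ConditionalResult:
    """Adjusted effect of a variant on the outcome, conditional on covariate(s)."""

    beta_adj: float
    se_adj: float
    gamma_adj: float
    z: float
    p: float
    scenario: str
    method_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConditionalExtras:
    """Optional cohort-level statistics beyond the standard summary columns.

    ``geno_freqs_covariate`` / ``geno_freqs_outcome`` are genotype frequencies
    stratified by case status of the (binary) covariate / outcome;
    ``mean_y2_cases`` / ``mean_y2_controls`` are means of the covariate among
    outcome cases / controls.  Whatever is supplied overrides the
    summary-statistic reconstruction.
    """

    geno_freqs_covariate: StratifiedGenoFreqs | None = None
    geno_freqs_outcome: StratifiedGenoFreqs | None = None
    mean_y2_cases: float | None = None
    mean_y2_controls: float | None = None


def _check_v(v: np.ndarray, label: str = "") -> None:
    w = np.linalg.eigvalsh(v)
    if w[0] <= 0 or w[0] / w[-1] < RCOND_THRESHOLD:
        raise CollinearityError(
            f"cross-product matrix V is singular or near-singular {label}".strip()
        )


def solve_block(
    cp: CrossProducts, beta1_marginal: float, gamma_m: float
) -> tuple[float, float]:
    """Solve the 2x2 block system for the adjusted (beta, gamma)."""
    v = np.array([[cp.xtx, cp.xty2], [cp.xty2, cp.y2ty2]])
    _check_v(v)
    rhs = np.array([cp.xtx * beta1_marginal, cp.y2ty2 * gamma_m])
    beta_adj, gamma_adj = np.linalg.solve(v, rhs)
    return float(beta_adj), float(gamma_adj)


def var_block_continuous(
    cp: CrossProducts, beta_adj: float, gamma_adj: float, n: int
) -> np.ndarray:
    """OLS covariance of the adjusted estimates (continuous outcome).

    (1/(n−2)) · V⁻¹ · (Y₁ᵀY₁ − β̂·XᵀY₁ − γ̂·Y₂ᵀY₁); requires ``cp.y1ty2``
    (the reconstructed Y₂ᵀY₁).
    """
    v = np.array([[cp.xtx, cp.xty2], [cp.xty2, cp.y2ty2]])
    _check_v(v)
    if not np.isfinite(cp.y1ty2):
        raise DomainError("y1ty2 is required for the continuous-outcome variance")
    rss = cp.y1ty1 - beta_adj * cp.xty1 - gamma_adj * cp.y1ty2
    if rss <= 0:
        raise DomainError(
            f"nonpositive residual sum of squares ({rss:.3g}); "
            "reconstructed cross-products are numerically inconsistent"
        )
    return rss / (n - 2) * np.linalg.inv(v)


def cov_beta1_gamma_m(
    cp: CrossProducts, var_beta1: float, var_gamma_m: float, n: int
) -> float:
    """Covariance of the two marginal estimates via the OLS-surrogate correlation.

    The correlation between the marginal logistic estimates is approximated by
    the correlation of their OLS counterparts (score and Wald tests are
    asymptotically equivalent), which is a ratio of reconstructed
    cross-products; it is then rescaled by the actual marginal standard errors.
    """
    if var_beta1 <= 0 or var_gamma_m <= 0:
        raise DomainError("marginal variances must be positive")
    if not np.isfinite(cp.y1ty2):
        raise DomainError("y1ty2 is required for the marginal-estimate covariance")
    var_y1 = cp.y1ty1 / (n - 1)
    num = var_y1 * cp.xty2 / (cp.xtx * cp.y2ty2)
    rss_x = cp.y1ty1 - cp.xty1**2 / cp.xtx
    rss_y2 = cp.y1ty1 - cp.y1ty2**2 / cp.y2ty2
    if rss_x <= 0 or rss_y2 <= 0:
        raise DomainError("degenerate residual sums of squares in the OLS surrogate")
    d1 = np.sqrt(rss_x / ((n - 1) * cp.xtx))
    d2 = np.sqrt(rss_y2 / ((n - 1) * cp.y2ty2))
    corr = float(np.clip(num / (d1 * d2), -1.0, 1.0))
    return corr * np.sqrt(var_beta1 * var_gamma_m)


def var_block_binary(
    cp: CrossProducts, var_beta1: float, var_gamma_m: float, cov_b1_gm: float
) -> np.ndarray:
    """Sandwich covariance V⁻¹ D Σ D V⁻¹ for logistic marginal inputs.

    Σ is the covariance of the marginal estimates; if it fails positive
    semidefiniteness its off-diagonal is clipped (with a warning).
    """
    if var_beta1 <= 0 or var_gamma_m <= 0:
        raise DomainError("marginal variances must be positive")
    bound = np.sqrt(var_beta1 * var_gamma_m)
    if abs(cov_b1_gm) > bound * (1 + 1e-12):
        warnings.warn("marginal covariance clipped to the PSD boundary", stacklevel=2)
        cov_b1_gm = np.sign(cov_b1_gm) * bound
    v = np.array([[cp.xtx, cp.xty2], [cp.xty2, cp.y2ty2]])
    _check_v(v)
    d = np.diag([cp.xtx, cp.y2ty2])
    sigma = np.array([[var_beta1, cov_b1_gm], [cov_b1_gm, var_gamma_m]])
    v_inv = np.linalg.inv(v)
    return v_inv @ d @ sigma @ d @ v_inv


def _variant_maf(
    outcome: SummaryRecord, covariate: SummaryRecord, freq_strategy: str
) -> float:
    if freq_strategy == "outcome":
        return outcome.maf
    if freq_strategy == "mean":
        eaf = 0.5 * (outcome.eaf + covariate.eaf)
        return min(eaf, 1.0 - eaf)
    if freq_strategy == "min":
        return min(outcome.maf, covariate.maf)
    raise DomainError(f"unknown freq_strategy {freq_strategy}")


def build_cross_products(
    outcome: SummaryRecord,
    covariate: SummaryRecord,
    rel: TraitRelationship,
    extras: ConditionalExtras | None = None,
    freq_strategy: str = "outcome",
) -> tuple[CrossProducts, list[str]]:
    """Reconstruct the scalar cross-products for one harmonized variant.

    All quantities are expressed at the outcome sample size n; covariate
    cross-products estimated at a different sample size are rescaled through
    their per-individual variances (a no-op when the sizes agree).
    """
    extras = extras or ConditionalExtras()
    flags: list[str] = ["hwe_xtx"]
    n = outcome.n
    maf = _variant_maf(outcome, covariate, freq_strategy)
    xtx = xtx_from_maf(n, maf)

    # outcome side
    if outcome.trait_type == "continuous":
        xty1 = xty_from_beta(xtx, outcome.beta)
        y1ty1 = yty_from_se(xtx, outcome.se, n, beta_marginal=outcome.beta)
    else:
        y1ty1 = y2ty2_binary(outcome.n_cases, n)
        freqs1 = extras.geno_freqs_outcome
        if freqs1 is None:
            freqs1 = estimate_stratified_geno_freqs(
                maf, outcome.beta, outcome.n_cases, outcome.n_controls
            )
            flags.append("reconstructed_outcome_geno_freqs")
        xty1 = xty2_binary(freqs1, outcome.n_cases, outcome.n_controls)

    # covariate side, rescaled to the outcome sample size
    scale = n / covariate.n
    if covariate.trait_type == "continuous":
        xty2 = xty_from_beta(xtx, covariate.beta)  # slope is sample-size free
        xtx_cov = xtx_from_maf(covariate.n, maf)
        sigma2_cov = xtx_cov * covariate.se**2  # per-individual residual variance
        y2ty2 = (n - 1) * sigma2_cov + covariate.beta**2 * xtx
    else:
        freqs2 = extras.geno_freqs_covariate
        if freqs2 is None:
            freqs2 = estimate_stratified_geno_freqs(
                maf, covariate.beta, covariate.n_cases, covariate.n_controls
            )
            flags.append("reconstructed_covariate_geno_freqs")
        y2ty2 = y2ty2_binary(covariate.n_cases, covariate.n) * scale
        xty2 = xty2_binary(freqs2, covariate.n_cases, covariate.n_controls) * scale

    # outcome-covariate cross-product
    if outcome.trait_type == "continuous":
        # identity-link relationship model: Y2'Y1 = gamma_m * Y2'Y2 exactly
        y1ty2 = rel.gamma_m * y2ty2
    else:
        if extras.mean_y2_cases is not None and extras.mean_y2_controls is not None:
            y1ty2 = y1ty2_binary_cont(
                outcome.n_cases, n, extras.mean_y2_cases, extras.mean_y2_controls
            )
        elif rel.source == "full":
            # OLS-surrogate slope of the 0/1 outcome on the covariate:
            # logistic slope damped by the outcome variance p(1-p)
            p_case = outcome.n_cases / n
            y1ty2 = rel.gamma_m * p_case * (1.0 - p_case) * y2ty2
            flags.append("y1ty2_from_gamma_m")
        else:
            raise InputError(
                "binary outcome needs covariate means among cases and controls "
                "(or a full-data relationship estimate to fall back on)"
            )

    cp = CrossProducts(
        xtx=xtx, xty1=xty1, xty2=xty2, y1ty1=y1ty1, y2ty2=y2ty2, n=n, y1ty2=y1ty2
    )
    return cp, flags


def approx_conditional(
    outcome: SummaryRecord,
    covariate: SummaryRecord,
    rel: TraitRelationship,
    extras: ConditionalExtras | None = None,
    cross_products: CrossProducts | None = None,
    freq_strategy: str = "outcome",
) -> ConditionalResult:
    """Adjusted variant effect on the outcome, conditional on the covariate.

    Dispatches on the (outcome, covariate) trait types; ``cross_products``
    may be supplied to bypass the summary-statistic reconstruction (e.g. exact
    centered cross-products computed from individual-level data, in which case
    the continuous/continuous result is exactly the individual-level OLS fit).
    Wald test: z = beta_adj / se_adj against the standard normal.
    """
    expected_link = "logit" if outcome.trait_type == "binary" else "identity"
    if rel.link != expected_link:
        raise InputError(
            f"relationship link {rel.link!r} inconsistent with "
            f"{outcome.trait_type} outcome"
        )
    scenario = {"continuous": "c", "binary": "b"}[outcome.trait_type] + {
        "continuous": "c",
        "binary": "b",
    }[covariate.trait_type]

    if cross_products is None:
        cp, flags = build_cross_products(outcome, covariate, rel, extras, freq_strategy)
    else:
        cp, flags = cross_products, ["user_cross_products"]
        if outcome.trait_type == "continuous" and not np.isfinite(cp.y1ty2):
            cp = CrossProducts(
                xtx=cp.xtx, xty1=cp.xty1, xty2=cp.xty2, y1ty1=cp.y1ty1,
                y2ty2=cp.y2ty2, n=cp.n, y1ty2=rel.gamma_m * cp.y2ty2,
            )

    if scenario == "bb" and outcome.maf < 0.01:
        flags.append("low_maf_binary_binary_bias")

    beta_adj, gamma_adj = solve_block(cp, outcome.beta, rel.gamma_m)
    if outcome.trait_type == "continuous":
        cov = var_block_continuous(cp, beta_adj, gamma_adj, cp.n)
    else:
        c = cov_beta1_gamma_m(cp, outcome.se**2, rel.gamma_m_var, cp.n)
        cov = var_block_binary(cp, outcome.se**2, rel.gamma_m_var, c)
    se_adj = float(np.sqrt(cov[0, 0]))
    if se_adj <= 0 or not np.isfinite(se_adj):
        raise DomainError("nonpositive adjusted standard error")
    z = beta_adj / se_adj
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ConditionalResult(
        beta_adj=beta_adj,
        se_adj=se_adj,
        gamma_adj=gamma_adj,
        z=float(z),
        p=max(p, np.finfo(float).tiny),
        scenario=scenario,
        method_flags=tuple(flags),
    )


def conditional_multi(
    outcome: SummaryRecord,
    covariates: list[SummaryRecord],
    rel_matrix: RelationshipMatrix,
    extras_list: list[ConditionalExtras | None] | None = None,
    freq_strategy: str = "outcome",
    overrides: dict | None = None,
) -> ConditionalResult:
    """Adjusted variant effect conditional on several covariates jointly.

    Generalizes the 2x2 block system: V gains one row/column per covariate
    (covariate cross-products taken from the joint phenotype fit), and the
    right-hand side uses the multivariable relationship coefficients.  With a
    single covariate this reduces exactly to :func:`approx_conditional`.

    ``overrides`` may supply exact centered cross-products (keys ``xtx``,
    ``xty`` — an array of genotype-covariate cross-products — ``xty1`` and
    ``y1ty1``) in place of the summary-statistic reconstructions; with exact
    values the continuous-outcome result equals the individual-level OLS fit.
    """
    m = len(covariates)
    if m < 1:
        raise InputError("need at least one covariate")
    if rel_matrix.gamma.shape != (m,):
        raise InputError("relationship matrix does not match the covariate count")
    expected_link = "logit" if outcome.trait_type == "binary" else "identity"
    if rel_matrix.link != expected_link:
        raise InputError("relationship link inconsistent with the outcome type")
    extras_list = extras_list or [None] * m
    overrides = overrides or {}

    n = outcome.n
    flags = ["user_cross_products"] if overrides else ["hwe_xtx"]
    # centered covariate Gram matrix, rescaled to the outcome sample size
    gram = rel_matrix.gram * (n - 1) / max(rel_matrix.n - 1, 1)
    y1ty = rel_matrix.y1ty * (n - 1) / max(rel_matrix.n - 1, 1)

    xty = np.empty(m)
    if "xty" in overrides:
        xty[:] = np.asarray(overrides["xty"], dtype=float)
    else:
        for j, cov_rec in enumerate(covariates):
            maf = _variant_maf(outcome, cov_rec, freq_strategy)
            xtx_j = xtx_from_maf(n, maf)
            if cov_rec.trait_type == "continuous":
                xty[j] = xty_from_beta(xtx_j, cov_rec.beta)
            else:
                ex = extras_list[j]
                freqs = ex.geno_freqs_covariate if ex is not None else None
                if freqs is None:
                    freqs = estimate_stratified_geno_freqs(
                        cov_rec.maf, cov_rec.beta, cov_rec.n_cases, cov_rec.n_controls
                    )
                    flags.append(f"reconstructed_covariate_geno_freqs[{j}]")
                xty[j] = xty2_binary(freqs, cov_rec.n_cases, cov_rec.n_controls) * (
                    n / cov_rec.n
                )

    maf0 = outcome.maf
    xtx = float(overrides.get("xtx", xtx_from_maf(n, maf0)))
    v = np.empty((m + 1, m + 1))
    v[0, 0] = xtx
    v[0, 1:] = v[1:, 0] = xty
    v[1:, 1:] = gram
    w = np.linalg.eigvalsh(v)
    if w[0] <= 0 or w[0] / w[-1] < RCOND_THRESHOLD:
        raise CollinearityError(
            f"{outcome.variant_id}: V singular; covariates may be collinear"
        )

    if "xty1" in overrides and "y1ty1" in overrides:
        xty1 = float(overrides["xty1"])
        y1ty1 = float(overrides["y1ty1"])
    elif outcome.trait_type == "continuous":
        xty1 = xty_from_beta(xtx, outcome.beta)
        y1ty1 = yty_from_se(xtx, outcome.se, n, beta_marginal=outcome.beta)
    else:
        y1ty1 = y2ty2_binary(outcome.n_cases, n)
        freqs1 = estimate_stratified_geno_freqs(
            maf0, outcome.beta, outcome.n_cases, outcome.n_controls
        )
        xty1 = xty2_binary(freqs1, outcome.n_cases, outcome.n_controls)
        flags.append("reconstructed_outcome_geno_freqs")

    rhs = np.concatenate([[xtx * outcome.beta], gram @ rel_matrix.gamma])
    b = np.linalg.solve(v, rhs)
    beta_adj = float(b[0])

    if outcome.trait_type == "continuous":
        # multivariable relationship fit: Y_j'Y1 = [Gram @ gamma]_j
        rss = y1ty1 - b @ np.concatenate([[xty1], gram @ rel_matrix.gamma])
        if rss <= 0:
            raise DomainError("nonpositive residual sum of squares")
        cov_b = rss / (n - m - 1) * np.linalg.inv(v)
    else:
        # sandwich: var(B) = V^{-1} J Sigma J' V^{-1}, J = diag(xtx) + Gram block
        sigma = np.zeros((m + 1, m + 1))
        sigma[0, 0] = outcome.se**2
        sigma[1:, 1:] = rel_matrix.cov * max(rel_matrix.n - 1, 1) / (n - 1)
        for j in range(m):
            cp_j = CrossProducts(
                xtx=xtx, xty1=xty1, xty2=xty[j], y1ty1=y1ty1,
                y2ty2=gram[j, j], n=n, y1ty2=y1ty[j],
            )
            sigma[0, j + 1] = sigma[j + 1, 0] = cov_beta1_gamma_m(
                cp_j, outcome.se**2, max(sigma[j + 1, j + 1], 1e-300), n
            )
        jmat = np.zeros((m + 1, m + 1))
        jmat[0, 0] = xtx
        jmat[1:, 1:] = gram
        v_inv = np.linalg.inv(v)
        cov_b = v_inv @ jmat @ sigma @ jmat @ v_inv

    se_adj = float(np.sqrt(cov_b[0, 0]))
    z = beta_adj / se_adj
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ConditionalResult(
        beta_adj=beta_adj,
        se_adj=se_adj,
        gamma_adj=float(b[1]),
        z=float(z),
        p=max(p, np.finfo(float).tiny),
        scenario=f"multi_m{m}",
        method_flags=tuple(flags),
    )


def adjust_table(
    outcome_records: list[SummaryRecord],
    covariate_records: list[SummaryRecord],
    rel: TraitRelationship,
    af_filter_alpha: float | None = 0.05,
    freq_strategy: str = "outcome",
) -> pd.DataFrame:
    """Vectorized entry point: harmonize, filter and adjust a variant table.

    Matches records by variant id, harmonizes alleles, optionally applies the
    Bonferroni allele-frequency filter, and runs the conditional estimator on
    every surviving pair.  Variants that fail harmonization or estimation are
    reported with a status instead of a result.
    """
    from .summary_io import af_discrepancy_filter

    cov_by_id = {r.variant_id: r for r in covariate_records}
    pairs: list[HarmonizedPair] = []
    rows: list[dict] = []
    for rec in outcome_records:
        other = cov_by_id.get(rec.variant_id)
        if other is None:
            rows.append({"variant_id": rec.variant_id, "status": "no_covariate_match"})
            continue
        try:
            pairs.append(harmonize(rec, other))
        except Exception as exc:
            rows.append({"variant_id": rec.variant_id, "status": f"harmonize: {exc}"})

    if af_filter_alpha is not None:
        kept, removed = af_discrepancy_filter(pairs, alpha=af_filter_alpha)
        for pair in removed:
            rows.append(
                {
                    "variant_id": pair.outcome.variant_id,
                    "status": "af_discrepancy",
                    "af_diff_p": pair.af_diff_p,
                }
            )
    else:
        kept = pairs

    for pair in kept:
        out = pair.outcome
        base = {
            "variant_id": out.variant_id,
            "effect_allele": out.effect_allele,
            "other_allele": out.other_allele,
            "eaf": out.eaf,
            "beta": out.beta,
            "se": out.se,
            "n": out.n,
            "flipped": pair.flipped,
            "af_diff_p": pair.af_diff_p,
        }
        try:
            res = approx_conditional(
                out, pair.covariate, rel, freq_strategy=freq_strategy
            )
        except Exception as exc:
            rows.append({**base, "status": f"estimation: {exc}"})
            continue
        rows.append(
            {
                **base,
                "status": "ok",
                "beta_adj": res.beta_adj,
                "se_adj": res.se_adj,
                "z_adj": res.z,
                "p_adj": res.p,
            }
        )
    return pd.DataFrame(rows)
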