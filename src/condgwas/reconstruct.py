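"""Reconstruct cross-products of genotype and traits from summary statistics.

All quantities are *centered*: ``xtx`` is the genotype's centered sum of
squares (≈ 2·n·MAF·(1−MAF) under Hardy–Weinberg equilibrium), ``xty`` the
centered genotype–trait cross-product, ``yty`` the trait's centered sum of
squares, and so on.  Intercepts of the underlying regressions are implicit in
the centering.

For a binary trait coded 0/1 the centered sum of squares has the exact
closed form n₁(1 − n₁/n) and the genotype cross-product follows from the
genotype frequencies stratified by case status, which — when a consortium does
not publish them — can be recovered from MAF, the marginal log-odds ratio and
the case/control counts under within-stratum Hardy–Weinberg equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DegenerateTraitError, DomainError, InfeasibleFrequencyError

__all__ = [
    "CrossProducts",
    "StratifiedGenoFreqs",
    "xtx_from_maf",
    "xty_from_beta",
    "yty_from_se",
    "y2ty2_binary",
    "xty2_binary",
    "estimate_stratified_geno_freqs",
    "y1ty2_binary_cont",
]


@dataclass
class CrossProducts:
    """Scalar sufficient statistics for the two-covariate block system.

    Attributes
    ----------
    xtx, xty1, xty2, y1ty1, y2ty2, y1ty2 : float
        Centered cross-products of the genotype X, outcome Y1 and
        covariate Y2.  ``y1ty2`` may be ``nan`` when not (yet) available.
    n : int
        Sample size the cross-products refer to.
    """

    xtx: float
    xty1: float
    xty2: float
    y1ty1: float
    y2ty2: float
    n: int
    y1ty2: float = float("nan")

    def __post_init__(self) -> None:
        if self.xtx < 0 or self.y1ty1 < 0 or self.y2ty2 < 0:
            raise DomainError("sums of squares must be nonnegative")
        if np.isfinite(self.y1ty2):
            bound = np.sqrt(self.y1ty1 * self.y2ty2)
            if abs(self.y1ty2) > bound * (1 + 1e-8) + 1e-12:
                raise DomainError(
                    "y1ty2 violates the Cauchy-Schwarz bound "
                    f"(|{self.y1ty2}| > {bound})"
                )


@dataclass
class StratifiedGenoFreqs:
    """Genotype frequencies P(X = i | case status j), a 3x2 column-stochastic table.

    Column 0 is controls, column 1 is cases; rows are genotypes 0, 1, 2.
    """

    p_ij: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p_ij, dtype=float)
        if p.shape != (3, 2):
            raise DomainError(f"expected a 3x2 table, got shape {p.shape}")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise DomainError("entries must lie in [0, 1]")
        colsums = p.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-8):
            raise DomainError(f"columns must sum to 1, got {colsums}")
        self.p_ij = p

    def mean_genotype(self, stratum: int) -> float:
        """E[X | case status = stratum] = P1j + 2 P2j."""
        return float(self.p_ij[1, stratum] + 2.0 * self.p_ij[2, stratum])


def xtx_from_maf(n: int, maf: float) -> float:
    """Centered genotype sum of squares 2·n·MAF·(1−MAF) under HWE."""
    if not 0.0 < maf <= 0.5:
        raise DomainError(f"MAF must lie in (0, 0.5], got {maf}")
    if n < 2:
        raise DomainError(f"need n >= 2, got {n}")
    return 2.0 * n * maf * (1.0 - maf)


def xty_from_beta(xtx: float, beta_marginal: float) -> float:
    """Invert the marginal OLS slope: XᵀY = XᵀX · β̂."""
    if xtx <= 0:
        raise DomainError("xtx must be positive")
    return xtx * beta_marginal


def yty_from_se(xtx: float, se_marginal: float, n: int, beta_marginal: float = 0.0) -> float:
    """Trait centered sum of squares implied by the marginal fit.

    The marginal residual variance identity gives the residual sum of squares
    (n−1)·XᵀX·SE(β̂)²; adding the fitted sum of squares β̂²·XᵀX yields the
    total YᵀY.  With the default ``beta_marginal=0`` only the residual part is
    returned (adequate when the marginal R² is negligible).
    """
    if xtx <= 0:
        raise DomainError("xtx must be positive")
    if se_marginal <= 0:
        raise DomainError("standard error must be positive")
    if n < 3:
        raise DomainError(f"need n >= 3, got {n}")
    return (n - 1) * xtx * se_marginal**2 + beta_marginal**2 * xtx


def y2ty2_binary(n_cases: int, n: int) -> float:
    """Centered sum of squares of a 0/1 trait: n₁·(1 − n₁/n). Exact."""
    if not 0 < n_cases < n:
        raise DegenerateTraitError(
            f"binary trait needs both classes, got {n_cases} cases of {n}"
        )
    return n_cases * (1.0 - n_cases / n)


def xty2_binary(freqs: StratifiedGenoFreqs, n_cases: int, n_controls: int) -> float:
    """Centered genotype × 0/1-trait cross-product from stratified genotype frequencies.

    XᵀY₂ ≈ n₁(P₁₁+2P₂₁) − n₁[n₀(P₁₀+2P₂₀) + n₁(P₁₁+2P₂₁)]/n.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise DegenerateTraitError("case and control counts must be positive")
    n = n_cases + n_controls
    m1 = freqs.mean_genotype(1)
    m0 = freqs.mean_genotype(0)
    return n_cases * m1 - n_cases * (n_controls * m0 + n_cases * m1) / n


def estimate_stratified_geno_freqs(
    maf: float, beta2: float, n_cases: int, n_controls: int
) -> StratifiedGenoFreqs:
    """Recover stratified genotype frequencies from summary statistics alone.

    Finds the unique stratum allele frequencies (p₀ controls, p₁ cases) with

    * Hardy–Weinberg genotype proportions within each stratum,
    * per-allele odds ratio exp(beta2) between strata:
      p₁/(1−p₁) = exp(beta2)·p₀/(1−p₀),
    * pooled allele frequency (n₀p₀ + n₁p₁)/n equal to ``maf``,

    by a monotone one-dimensional root find in p₀.
    """
    if not 0.0 < maf < 0.5:
        raise DomainError(f"MAF must lie in (0, 0.5), got {maf}")
    if not np.isfinite(beta2):
        raise DomainError("beta2 must be finite")
    if n_cases <= 0 or n_controls <= 0:
        raise DegenerateTraitError("case and control counts must be positive")
    n = n_cases + n_controls
    odds_ratio = np.exp(beta2)

    def p1_of(p0: float) -> float:
        o = odds_ratio * p0 / (1.0 - p0)
        return o / (1.0 + o)

    def pooled_minus_maf(p0: float) -> float:
        return (n_controls * p0 + n_cases * p1_of(p0)) / n - maf

    lo, hi = 1e-12, 1.0 - 1e-12
    f_lo, f_hi = pooled_minus_maf(lo), pooled_minus_maf(hi)
    if f_lo > 0 or f_hi < 0:
        raise InfeasibleFrequencyError(
            f"no stratum frequencies reproduce pooled MAF {maf} with log-OR {beta2}"
        )
    p0 = brentq(pooled_minus_maf, lo, hi, xtol=1e-14)
    p1 = p1_of(p0)
    table = np.column_stack([_hwe_column(p0), _hwe_column(p1)])
    return StratifiedGenoFreqs(table)


def _hwe_column(p: float) -> np.ndarray:
    return np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2])


def y1ty2_binary_cont(
    n_cases: int, n: int, mean_y2_cases: float, mean_y2_controls: float
) -> float:
    """Centered Y₁ᵀY₂ for binary Y₁ from stratum means of Y₂.

    Y₁ᵀY₂ = n·Cov(Y₁, Y₂) = n₁(1 − n₁/n)[Mean(Y₂|Y₁=1) − Mean(Y₂|Y₁=0)].
    """
    if not 0 < n_cases < n:
        raise DegenerateTraitError(
            f"binary trait needs both classes, got {n_cases} cases of {n}"
        )
    return n_cases * (1.0 - n_cases / n) * (mean_y2_cases - mean_y2_controls)
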