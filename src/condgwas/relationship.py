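"""Estimate the outcome-covariate relationship (the coefficient gamma_m).

The conditional estimator needs one quantity that marginal GWAS summary
statistics cannot provide: the regression coefficient of the outcome on the
adjustment covariate (identity link for a continuous outcome, logit link for a
binary one).  Three provenances are supported:

* ``full``    — fitted on the complete phenotype sample;
* ``subset``  — fitted on a random subsample (what a single participating
  cohort of a consortium could supply);
* ``literature`` — a point estimate taken from a published report, with an
  optional variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import oracle
from .errors import DomainError, InputError

__all__ = [
    "TraitRelationship",
    "PhenotypeTable",
    "RelationshipMatrix",
    "LITERATURE_CV",
    "estimate_gamma_m",
    "subset_gamma_m",
    "literature_gamma_m",
    "pairwise_relationships",
]

#: assumed coefficient of variation when a literature estimate comes without a
#: variance: var defaults to (LITERATURE_CV * gamma_m)^2
LITERATURE_CV = 0.1


@dataclass(frozen=True)
class TraitRelationship:
    """gamma_m with its sampling variance, link and provenance."""

    gamma_m: float
    gamma_m_var: float
    link: str = "identity"
    source: str = "full"
    n_rel: int = 0

    def __post_init__(self) -> None:
        if self.gamma_m_var <= 0:
            raise DomainError("gamma_m_var must be positive")
        if self.link not in ("identity", "logit"):
            raise DomainError(f"unknown link {self.link}")
        if self.source not in ("full", "subset", "literature"):
            raise DomainError(f"unknown source {self.source}")


@dataclass
class PhenotypeTable:
    """Individual-level outcome and covariate phenotypes.

    ``y1`` is the outcome; ``y2`` holds one column per covariate.  Rows with
    missing values are removed (listwise deletion) and counted.
    """

    y1: np.ndarray
    y2: np.ndarray
    n_dropped: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        y1 = np.asarray(self.y1, dtype=float)
        y2 = np.asarray(self.y2, dtype=float)
        if y2.ndim == 1:
            y2 = y2[:, None]
        if len(y1) != len(y2):
            raise InputError("outcome and covariates have different lengths")
        ok = np.isfinite(y1) & np.isfinite(y2).all(axis=1)
        self.n_dropped = int((~ok).sum())
        self.y1, self.y2 = y1[ok], y2[ok]
        n, m = self.y2.shape
        if n < 10 * (m + 1):
            raise InputError(f"need at least {10 * (m + 1)} complete rows, have {n}")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, outcome: str, covariates: list[str]
    ) -> "PhenotypeTable":
        return cls(df[outcome].to_numpy(), df[covariates].to_numpy())

    @property
    def n(self) -> int:
        return len(self.y1)

    @property
    def m(self) -> int:
        return self.y2.shape[1]


def _fit(y1: np.ndarray, y2: np.ndarray, link: str) -> oracle.FitResult:
    design = np.column_stack([np.ones(len(y1)), y2])
    if link == "identity":
        return oracle.fit_ols(y1, design)
    if link == "logit":
        return oracle.fit_logistic(y1, design)
    raise DomainError(f"unknown link {link}")


def estimate_gamma_m(
    table: PhenotypeTable, link: str = "identity", source: str = "full"
) -> TraitRelationship:
    """Fit outcome ~ covariate on individual-level data.

    Identity link is OLS; logit link is maximum-likelihood logistic
    regression.  Only the first covariate column is used (see
    :func:`pairwise_relationships` for the joint multi-covariate fit).
    """
    y2 = table.y2[:, 0]
    if np.var(y2) == 0:
        raise InputError("covariate has zero variance")
    fit = _fit(table.y1, y2, link)
    return TraitRelationship(
        gamma_m=float(fit.coef[1]),
        gamma_m_var=float(fit.cov[1, 1]),
        link=link,
        source=source,
        n_rel=table.n,
    )


def subset_gamma_m(
    table: PhenotypeTable, fraction: float, seed: int, link: str = "identity"
) -> TraitRelationship:
    """gamma_m from a simple random subsample of the phenotype table."""
    if not 0.0 < fraction <= 1.0:
        raise DomainError("fraction must lie in (0, 1]")
    k = int(round(fraction * table.n))
    if k < 30:
        raise InputError(f"subsample of {k} rows is too small (need >= 30)")
    if k == table.n:
        return estimate_gamma_m(table, link=link, source="subset")
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.n, size=k, replace=False)
    sub = PhenotypeTable(table.y1[idx], table.y2[idx])
    return estimate_gamma_m(sub, link=link, source="subset")


def literature_gamma_m(
    value: float, variance: float | None = None, link: str = "identity"
) -> TraitRelationship:
    """Wrap a published point estimate of gamma_m.

    When no variance is reported, defaults to ``(LITERATURE_CV * value)^2``
    with a warning — published reports often omit it, and the adjusted SE is
    dominated by other terms in typical applications.
    """
    if not np.isfinite(value):
        raise DomainError("gamma_m must be finite")
    if variance is None:
        variance = max((LITERATURE_CV * value) ** 2, 1e-12)
        warnings.warn(
            "no variance supplied for the literature gamma_m; defaulting to "
            f"(0.1*gamma_m)^2 = {variance:.3g}",
            stacklevel=2,
        )
    return TraitRelationship(
        gamma_m=value, gamma_m_var=variance, link=link, source="literature", n_rel=0
    )


@dataclass
class RelationshipMatrix:
    """Joint relationship information for multi-covariate adjustment.

    ``gamma`` and ``cov`` come from the multivariable outcome ~ covariates
    fit; ``gram`` holds the centered covariate cross-products YⱼᵀYₖ and
    ``y1ty`` the centered outcome-covariate cross-products Y₁ᵀYⱼ.
    """

    gamma: np.ndarray
    cov: np.ndarray
    gram: np.ndarray
    y1ty: np.ndarray
    y1ty1: float
    link: str
    n: int
    source: str = "full"


def pairwise_relationships(
    table: PhenotypeTable, link: str = "identity", source: str = "full"
) -> RelationshipMatrix:
    """Joint multivariable relationship fit plus covariate cross-products.

    The multivariable coefficients (not pairwise marginal slopes) are
    returned: the block system needs joint cross-products, and marginal
    slopes would double-count variance shared between covariates.
    """
    yc = table.y2 - table.y2.mean(axis=0)
    gram = yc.T @ yc
    w = np.linalg.eigvalsh(gram)
    if w[0] <= max(w[-1], 1.0) * 1e-12:
        raise InputError("covariates are collinear")
    fit = _fit(table.y1, table.y2, link)
    y1c = table.y1 - table.y1.mean()
    return RelationshipMatrix(
        gamma=fit.coef[1:].copy(),
        cov=fit.cov[1:, 1:].copy(),
        gram=gram,
        y1ty=yc.T @ y1c,
        y1ty1=float(y1c @ y1c),
        link=link,
        n=table.n,
        source=source,
    )
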