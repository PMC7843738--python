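"""Gold-standard individual-level model fits.

These are the reference fits of the marginal models (trait ~ variant), the
trait-relationship model (outcome ~ covariate) and the adjusted model
(outcome ~ variant + covariate) on individual-level data, against which the
summary-statistic approximation is benchmarked.  Identity link is closed-form
ordinary least squares; logit link is maximum likelihood via iteratively
reweighted least squares (IRLS).

Hand-rolled rather than delegated to statsmodels because simulation grids call
them thousands of times per cell; tests cross-check both fitters against
statsmodels on fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, DomainError, SeparationError

__all__ = ["FitResult", "fit_ols", "fit_logistic"]


@dataclass
class FitResult:
    """Coefficients and covariance of one individual-level GLM fit.

    ``coef[j]`` corresponds to the j-th column of the design matrix.
    ``sigma2`` is the residual variance (identity link only, divisor n − p);
    ``loglik`` is the maximized log-likelihood (logit link only).
    """

    coef: np.ndarray
    cov: np.ndarray
    n: int
    sigma2: float | None = None
    loglik: float | None = None
    se: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.se = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def _as_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def fit_ols(y: np.ndarray, X: np.ndarray) -> FitResult:
    """Ordinary least squares of ``y`` on the columns of ``X``.

    No intercept is added; pass a column of ones (or centered data) as
    appropriate.  Residual variance uses the n − p divisor.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X)
    n, p = X.shape
    if n <= p:
        raise DomainError(f"need n > p, got n={n}, p={p}")
    xtx = X.T @ X
    # rank check via eigenvalues of the (small) Gram matrix
    w = np.linalg.eigvalsh(xtx)
    if w[0] <= w[-1] * 1e-12:
        raise DomainError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    return FitResult(coef=coef, cov=sigma2 * xtx_inv, n=n, sigma2=sigma2)


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> FitResult:
    """Maximum-likelihood logistic regression of a 0/1 vector on ``X``.

    IRLS starting from zero coefficients with step-halving on likelihood
    decrease; covariance is the inverse observed (= expected, canonical link)
    information at the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X)
    n, p = X.shape
    if not np.isin(y, (0.0, 1.0)).all():
        raise DomainError("outcome must be 0/1")
    if y.min() == y.max():
        raise DomainError("outcome has a single class")

    beta = np.zeros(p)
    ll = _loglik(y, X, beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _expit(eta)
        w = mu * (1.0 - mu)
        if w.max() < 1e-10:
            raise SeparationError("fitted probabilities collapsed to 0/1")
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise SeparationError("singular information matrix") from exc
        # step-halving: never accept a material likelihood decrease
        new_ll = _loglik(y, X, beta + step)
        halvings = 0
        while new_ll < ll - 1e-10 and halvings < 30:
            step *= 0.5
            new_ll = _loglik(y, X, beta + step)
            halvings += 1
        beta = beta + step
        converged = np.max(np.abs(step)) < tol
        ll = new_ll
        if converged:
            break
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    if np.max(np.abs(beta)) > 30.0:
        raise SeparationError("diverging coefficients suggest separation")
    mu = _expit(X @ beta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    return FitResult(coef=beta, cov=np.linalg.inv(info), n=n, loglik=ll)


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-eta))


def _loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())
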