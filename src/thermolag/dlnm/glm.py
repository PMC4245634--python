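"""Poisson log-link regression fitted by iteratively reweighted least squares."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.special import gammaln

__all__ = ["FitResult", "fit_poisson", "poisson_loglik", "poisson_deviance"]


def poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Exact Poisson log-likelihood at linear predictor eta (log rate)."""
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of a Poisson log-link regression.

    ``cov`` is the inverse observed/expected information X'WX (they
    coincide for the canonical log link); ``aic = -2*loglik + 2*p``.
    ``term_slices`` maps design block names (e.g. "crossbasis") to column
    slices so downstream predictions can pull the right coefficients.
    """

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    deviance: float
    n: int
    converged: bool
    n_iter: int
    names: tuple[str, ...] = ()
    term_slices: dict = field(default_factory=dict, compare=False)
    dispersion: float = 1.0

    @property
    def n_params(self) -> int:
        return len(self.coef)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {', '.join(bad)}")


def fit_poisson(X: np.ndarray, y: np.ndarray, names: list[str] | None = None,
                tol: float = 1e-10, max_iter: int = 100,
                quasi: bool = False) -> FitResult:
    """IRLS Poisson fit.

    Convergence when the relative deviance change drops below ``tol``
    (default 1e-10) or after ``max_iter`` iterations (flagged, not
    raised).  With ``quasi=True`` the covariance is scaled by the Pearson
    dispersion estimate (point estimates unchanged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response and design have different lengths")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("design and response must be finite")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    _check_rank(X, list(names))

    # start from the intercept-only rate when an all-ones column exists
    beta = np.zeros(p)
    ones = np.where(np.all(X == 1.0, axis=0))[0]
    mean_y = max(y.mean(), 1e-8)
    if len(ones):
        beta[ones[0]] = np.log(mean_y)
    eta = X @ beta
    mu = np.exp(eta)
    dev = poisson_deviance(y, mu)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = mu  # canonical link: var = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        try:
            c = cho_factor(XtW @ X)
            beta = cho_solve(c, XtW @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(np.sqrt(W)[:, None] * X,
                                   np.sqrt(W) * z, rcond=None)[0]
        eta = X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = poisson_deviance(y, mu)
        if abs(new_dev - dev) / (abs(dev) + 0.1) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev

    info = (X.T * mu) @ X
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    dispersion = 1.0
    if quasi:
        pearson = float(np.sum((y - mu) ** 2 / mu))
        dispersion = max(pearson / max(n - p, 1), 1e-12)
        cov = cov * dispersion
    ll = poisson_loglik(y, eta)
    return FitResult(coef=beta, cov=cov, loglik=ll, aic=-2.0 * ll + 2.0 * p,
                     deviance=dev, n=n, converged=converged, n_iter=it,
                     names=tuple(names), dispersion=dispersion)
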