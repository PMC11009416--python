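"""Quasi-Poisson regression and quasi-likelihood estimation.

The quasi-Poisson model for counts y_i specifies only the first two
moments: E(y_i) = mu_i = exp(x_i' beta) and Var(y_i) = gamma * mu_i,
where gamma >= 1 is the overdispersion parameter.  Coefficients are
estimated by solving the quasi-score equations with iteratively
reweighted least squares (IWLS); the dispersion is estimated afterwards
from Pearson residuals and does not affect the coefficient estimates
(it cancels in the score).

Conventions used throughout the package:

* the design matrix ``X`` has an intercept column of ones first, so its
  dimension is n x (p+1) with ``p`` counting the non-intercept
  regressors;
* the IWLS weight matrix is W = diag(mu_hat), so the weighted
  cross-product is F = X' diag(mu_hat) X and the coefficient covariance
  is gamma_hat * F^{-1} with the dispersion carried as a separate
  scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, RankDeficiencyError, ValidationError

# Lower clamp on fitted means: keeps the working response finite for
# extreme linear predictors without perturbing any realistic fit.
_MU_FLOOR = 1e-10
# |eta| beyond this overflows exp() in float64.
_ETA_CAP = 700.0

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100


@dataclass(frozen=True)
class CountDataset:
    """A count-response regression dataset.

    Parameters
    ----------
    X : ndarray, shape (n, p+1)
        Design matrix whose first column is the intercept (all ones).
    y : ndarray, shape (n,)
        Non-negative integer counts.
    names : tuple of str
        Labels for the p non-intercept regressors.
    """

    X: np.ndarray
    y: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D matrix")
        n, q = X.shape
        if y.shape != (n,):
            raise ValidationError(
                f"y has length {y.shape}, expected ({n},) to match X"
            )
        if not np.allclose(X[:, 0], 1.0):
            raise ValidationError("first column of X must be the intercept (all ones)")
        if np.any(y < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(y, np.round(y)):
            raise ValidationError("counts must be integers")
        if n <= q:
            raise ValidationError(
                f"need n > p+1 (got n={n}, p+1={q})"
            )
        if np.linalg.matrix_rank(X) < q:
            raise RankDeficiencyError("design matrix is rank deficient")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", np.asarray(np.round(y), dtype=float))
        names = tuple(self.names) if self.names else tuple(
            f"x{j}" for j in range(1, q)
        )
        if len(names) != q - 1:
            raise ValidationError(
                f"got {len(names)} regressor names for {q - 1} regressors"
            )
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        """Number of non-intercept regressors."""
        return self.X.shape[1] - 1


@dataclass
class QLEFit:
    """Result of a quasi-likelihood (IWLS) fit."""

    beta: np.ndarray
    mu: np.ndarray
    eta: np.ndarray
    F: np.ndarray
    W_diag: np.ndarray
    gamma_hat: float
    n_iter: int
    converged: bool
    tol: float
    names: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        labels = ("intercept",) + tuple(self.names)
        return {
            "estimator": "QLE",
            "coefficients": dict(zip(labels, map(float, self.beta))),
            "gamma_hat": float(self.gamma_hat),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "tol": float(self.tol),
        }


def quasi_loglik(y, mu, gamma: float = 1.0) -> float:
    """Quasi-log-likelihood sum_i (1/gamma) * (y_i log mu_i - mu_i).

    The convention 0 * log(mu) = 0 never arises because mu > 0 is
    required, but y_i = 0 simply drops the log term.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValidationError("y and mu must have the same length")
    if np.any(mu <= 0):
        raise ValidationError("mu must be strictly positive")
    if gamma <= 0:
        raise ValidationError("gamma must be strictly positive")
    return float(np.sum(y * np.log(mu) - mu) / gamma)


def _mu_from_eta(eta: np.ndarray) -> np.ndarray:
    return np.maximum(np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP)), _MU_FLOOR)


def fit_qle(
    data: CountDataset,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> QLEFit:
    """Fit the quasi-Poisson model by IWLS.

    Starting values come from ordinary least squares on log(y + 0.5).
    At each step the update is beta = F^{-1} X' W m with W = diag(mu),
    F = X'WX and working response m_i = eta_i + (y_i - mu_i)/mu_i.
    Convergence is declared when the maximum relative coefficient
    change falls below ``tol``.

    Raises
    ------
    ConvergenceError
        If ``max_iter`` is exhausted; the exception carries the last
        iterate.
    RankDeficiencyError
        If F becomes singular at any iteration.
    """
    X, y = data.X, data.y
    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = _mu_from_eta(eta)
        w = mu  # W = diag(mu); 1/gamma cancels in the update
        m = eta + (y - mu) / mu
        Xw = X * w[:, None]
        F = X.T @ Xw
        try:
            beta_new = np.linalg.solve(F, Xw.T @ m)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(
                f"singular weighted cross-product at iteration {n_iter}"
            ) from exc
        delta = np.max(
            np.abs(beta_new - beta) / np.maximum(np.abs(beta), 1e-8)
        )
        beta = beta_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"IWLS did not converge in {max_iter} iterations",
            last_beta=beta,
            n_iter=max_iter,
        )

    eta = X @ beta
    mu = _mu_from_eta(eta)
    F = X.T @ (X * mu[:, None])
    gamma_hat = estimate_dispersion(y, mu, data.p)
    return QLEFit(
        beta=beta,
        mu=mu,
        eta=eta,
        F=F,
        W_diag=mu.copy(),
        gamma_hat=gamma_hat,
        n_iter=n_iter,
        converged=True,
        tol=tol,
        names=data.names,
    )


def estimate_dispersion(y, mu, p: int) -> float:
    """Pearson dispersion estimate chi^2 / (n - p - 1).

    chi^2 = sum_i (y_i - mu_i)^2 / mu_i is the Pearson statistic under
    the quasi-Poisson variance Var = gamma * mu.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValidationError("y and mu must have the same length")
    n = len(y)
    dof = n - p - 1
    if dof <= 0:
        raise ValidationError(
            f"no residual degrees of freedom (n={n}, p+1={p + 1})"
        )
    return float(np.sum((y - mu) ** 2 / mu) / dof)


def qle_cov_mse(F: np.ndarray, gamma: float):
    """Covariance gamma * F^{-1} and scalar MSE gamma * sum_j 1/lambda_j.

    The scalar MSE is the trace of the covariance, expressed through
    the eigenvalues lambda_j of F.
    """
    F = np.asarray(F, dtype=float)
    if gamma <= 0:
        raise ValidationError("gamma must be strictly positive")
    lambdas = np.linalg.eigvalsh(F)
    if np.any(lambdas <= 0):
        worst = float(lambdas.min())
        raise RankDeficiencyError(
            f"F is singular or indefinite (smallest eigenvalue {worst:.3e})"
        )
    cov = gamma * np.linalg.inv(F)
    mse = float(gamma * np.sum(1.0 / lambdas))
    return cov, mse


def score(data: CountDataset, beta: np.ndarray) -> np.ndarray:
    """Quasi-score X'(y - mu) at beta (gamma-free part).

    Zero at the quasi-likelihood optimum; used to verify convergence.
    """
    mu = _mu_from_eta(data.X @ beta)
    return data.X.T @ (data.y - mu)
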