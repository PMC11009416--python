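"""Ridge (shrinkage) estimation for the quasi-Poisson model.

The ridge estimator beta_k = (F + kI)^{-1} F beta_QLE counters
multicollinearity by shrinking the quasi-likelihood estimate toward
zero, trading bias for variance.  All of its finite-sample moments are
diagonal in the canonical form obtained by rotating with the
eigenvectors T of F = X'WX:

* bias(beta_k)  = -k T Lambda_k^{-1} T' beta
* cov(beta_k)   = gamma T Lambda_k^{-1} Lambda Lambda_k^{-1} T'
* MMSE          = cov + bias bias'
* scalar MSE(k) = M1(k) + M2(k)
                = gamma sum_j lambda_j/(lambda_j+k)^2
                  + k^2 sum_j alpha_j^2/(lambda_j+k)^2

with Lambda_k = diag(lambda_j + k) and alpha = T' beta.  M1 is the
variance term (monotonically decreasing in k) and M2 the squared-bias
term (monotonically increasing); their sum always dips below the
unpenalized MSE for some k > 0.

All p+1 coefficients, including the intercept, are penalized by
default; pass ``penalize_intercept=False`` to ridge_coefficients to
exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class EigenSystem:
    """Canonical form of a fit: eigen-decomposition of F plus rotated
    coefficients alpha = T' beta."""

    lambdas: np.ndarray  # eigenvalues of F, descending
    T: np.ndarray        # orthogonal, columns are eigenvectors
    alpha: np.ndarray    # rotated coefficients


@dataclass
class RidgeFit:
    """A ridge fit at a specific biasing parameter k."""

    k: float
    rule: str
    beta_k: np.ndarray
    bias: np.ndarray
    cov: np.ndarray
    mmse: np.ndarray
    m1: float
    m2: float
    mse: float
    mu: np.ndarray | None = None
    gamma_hat: float | None = None
    names: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        labels = ("intercept",) + tuple(self.names)
        out = {
            "estimator": "QPRRE",
            "rule": self.rule,
            "k": float(self.k),
            "coefficients": dict(zip(labels, map(float, self.beta_k))),
            "mse": float(self.mse),
            "mse_variance_term": float(self.m1),
            "mse_bias_term": float(self.m2),
        }
        if self.gamma_hat is not None:
            out["gamma_hat"] = float(self.gamma_hat)
        return out


def eigen_decompose(F: np.ndarray, beta_qle: np.ndarray) -> EigenSystem:
    """Eigen-decompose F and rotate beta into canonical coordinates.

    Eigenvalues are sorted descending.  Each eigenvector's sign is
    fixed so its largest-magnitude entry is positive, making the
    decomposition deterministic; every downstream quantity is
    invariant to this convention.
    """
    F = np.asarray(F, dtype=float)
    if not np.allclose(F, F.T, atol=_SYM_TOL):
        raise ValidationError("F must be symmetric")
    lambdas, T = np.linalg.eigh(F)
    order = np.argsort(lambdas)[::-1]
    lambdas = lambdas[order]
    T = T[:, order]
    for j in range(T.shape[1]):
        i = np.argmax(np.abs(T[:, j]))
        if T[i, j] < 0:
            T[:, j] = -T[:, j]
    alpha = T.T @ np.asarray(beta_qle, dtype=float)
    return EigenSystem(lambdas=lambdas, T=T, alpha=alpha)


def ridge_coefficients(
    F: np.ndarray,
    beta_qle: np.ndarray,
    k: float,
    penalize_intercept: bool = True,
) -> np.ndarray:
    """Ridge coefficients (F + kI)^{-1} F beta_QLE.

    In canonical coordinates component j is shrunk by
    lambda_j / (lambda_j + k).  With ``penalize_intercept=False`` the
    (0,0) entry of the penalty is zeroed so the intercept is left
    unshrunk.
    """
    if k < 0:
        raise ValidationError("biasing parameter k must be non-negative")
    F = np.asarray(F, dtype=float)
    beta_qle = np.asarray(beta_qle, dtype=float)
    P = np.eye(F.shape[0])
    if not penalize_intercept:
        P[0, 0] = 0.0
    return np.linalg.solve(F + k * P, F @ beta_qle)


def ridge_moments(eig: EigenSystem, gamma: float, k: float, beta: np.ndarray):
    """Exact bias, covariance, matrix MSE and scalar MSE of the ridge
    estimator at k.

    ``beta`` is the coefficient vector at which the bias is evaluated:
    the QLE estimate for data fits, the true coefficients inside
    simulations.

    Returns
    -------
    (bias, cov, mmse, m1, m2, mse)
    """
    if k < 0:
        raise ValidationError("k must be non-negative")
    if gamma <= 0:
        raise ValidationError("gamma must be strictly positive")
    lam = eig.lambdas
    T = eig.T
    beta = np.asarray(beta, dtype=float)
    alpha = T.T @ beta
    denom = lam + k

    bias = -k * (T @ (alpha / denom))
    cov = gamma * (T @ ((lam / denom**2)[:, None] * T.T))
    mmse = cov + np.outer(bias, bias)
    m1 = float(gamma * np.sum(lam / denom**2))
    m2 = float(k**2 * np.sum(alpha**2 / denom**2))
    return bias, cov, mmse, m1, m2, m1 + m2


def mse_derivative(eig: EigenSystem, gamma: float, k: float):
    """First derivatives of the scalar-MSE components at k.

    M1'(k) = -2 gamma sum_j lambda_j/(lambda_j+k)^3   (always < 0)
    M2'(k) =  2 k sum_j alpha_j^2 lambda_j/(lambda_j+k)^3  (>= 0)
    total  = -2 sum_j lambda_j (gamma - k alpha_j^2)/(lambda_j+k)^3

    The total is strictly negative whenever k < gamma / max_j alpha_j^2,
    which is why some k > 0 always beats k = 0.
    """
    if k < 0:
        raise ValidationError("k must be non-negative")
    lam = eig.lambdas
    a2 = eig.alpha**2
    denom3 = (lam + k) ** 3
    m1p = float(-2.0 * gamma * np.sum(lam / denom3))
    m2p = float(2.0 * k * np.sum(a2 * lam / denom3))
    total = float(-2.0 * np.sum(lam * (gamma - k * a2) / denom3))
    return m1p, m2p, total
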