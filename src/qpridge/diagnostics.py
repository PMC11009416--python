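"""Multicollinearity diagnostics and predictive assessment.

Condition index of the design cross-product, leverages of the weighted
(ridge) hat matrix, the PRESS criterion built from Pearson residuals,
and k-fold cross-validation on the response scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .exceptions import ConvergenceError, QPRidgeError, ValidationError
from .quasipoisson import CountDataset, QLEFit, fit_qle
from .ridge import RidgeFit
from .kparams import fit_qprre


@dataclass
class DiagnosticsReport:
    condition_index: float
    press: float
    cv: float
    hat_diag: np.ndarray

    def to_dict(self) -> dict:
        return {
            "condition_index": float(self.condition_index),
            "press": float(self.press),
            "cv": float(self.cv),
            "hat_diag": [float(h) for h in self.hat_diag],
        }


def condition_index(X: np.ndarray) -> float:
    """Condition index sqrt(lambda_max / lambda_min) of X'X.

    Computed on the raw, intercept-augmented design matrix without
    centering or scaling.  Values above 30 indicate severe
    multicollinearity.  A singular cross-product yields +inf with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    lambdas = np.linalg.eigvalsh(X.T @ X)
    lmin, lmax = float(lambdas[0]), float(lambdas[-1])
    if lmin <= 0:
        warnings.warn("X'X is rank deficient; condition index is infinite")
        return float("inf")
    return float(np.sqrt(lmax / lmin))


def hat_diagonals(X: np.ndarray, W_diag: np.ndarray, k: float = 0.0) -> np.ndarray:
    """Leverages h_ii of the weighted ridge hat matrix.

    H = W^{1/2} X (X'WX + kI)^{-1} X' W^{1/2}.  At k = 0 this is the
    weighted-projection hat matrix with trace p+1; as k grows all
    leverages shrink to zero.
    """
    if k < 0:
        raise ValidationError("k must be non-negative")
    X = np.asarray(X, dtype=float)
    w = np.asarray(W_diag, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("weights must be strictly positive")
    Xs = X * np.sqrt(w)[:, None]
    A = Xs.T @ Xs + k * np.eye(X.shape[1])
    try:
        B = np.linalg.solve(A, Xs.T)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("X'WX + kI is singular") from exc
    return np.einsum("ij,ji->i", Xs, B)


def press(data: CountDataset, fit: QLEFit | RidgeFit) -> float:
    """PRESS criterion (1/n) sum_i chi_i^2 / (1 - h_ii)^2.

    chi_i = (y_i - mu_i) / sqrt(gamma * mu_i) are Pearson residuals at
    the supplied fit's means (ridge means for a ridge fit); the
    leverages come from the hat matrix at the fit's own k, with
    weights diag(mu).
    """
    if isinstance(fit, RidgeFit):
        mu, gamma, k = fit.mu, fit.gamma_hat, fit.k
    else:
        mu, gamma, k = fit.mu, fit.gamma_hat, 0.0
    if gamma is None or gamma <= 0:
        raise ValidationError("fit must carry a positive dispersion estimate")
    h = hat_diagonals(data.X, mu, k)
    if np.any(h >= 1):
        raise ValidationError("a leverage h_ii >= 1; PRESS undefined")
    chi = (data.y - mu) / np.sqrt(gamma * mu)
    return float(np.mean(chi**2 / (1.0 - h) ** 2))


def kfold_cv(
    data: CountDataset,
    rule: str | None = None,
    k: float | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """k-fold cross-validated mean squared prediction error.

    Rows are partitioned by a seeded shuffle; the chosen estimator
    ("QLE" via ``rule=None, k=0`` semantics, a named ridge rule, or a
    fixed k) is refit on each training set and the held-out responses
    are scored by (y_i - mu_hat_i)^2 on the response scale.  Folds
    where the fit fails to converge are skipped with a warning.
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    n = data.n
    if n / folds < 1 or (n - int(np.ceil(n / folds))) <= data.p + 1:
        raise ValidationError("training folds would have n_train <= p+1")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_errs = []
    n_failed = 0
    for train, test in splitter.split(data.X):
        sub = CountDataset(X=data.X[train], y=data.y[train], names=data.names)
        try:
            if rule is None and k is None:
                beta = fit_qle(sub).beta
            else:
                beta = fit_qprre(sub, rule=rule, k=k).beta_k
        except QPRidgeError as exc:
            n_failed += 1
            warnings.warn(f"fold skipped: {exc}")
            continue
        mu_hat = np.exp(np.clip(data.X[test] @ beta, -700, 700))
        sq_errs.extend(((data.y[test] - mu_hat) ** 2).tolist())
    if n_failed == folds:
        raise ConvergenceError("every cross-validation fold failed to converge")
    return float(np.mean(sq_errs))


def diagnose(
    data: CountDataset,
    rule: str | None = None,
    k: float | None = None,
    folds: int = 5,
    seed: int = 0,
) -> DiagnosticsReport:
    """Full diagnostics report for one estimator choice."""
    if rule is None and k is None:
        fit = fit_qle(data)
        k_eff = 0.0
    else:
        fit = fit_qprre(data, rule=rule, k=k)
        k_eff = fit.k
    return DiagnosticsReport(
        condition_index=condition_index(data.X),
        press=press(data, fit),
        cv=kfold_cv(data, rule=rule, k=k, folds=folds, seed=seed),
        hat_diag=hat_diagonals(data.X, fit.mu, k_eff),
    )
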