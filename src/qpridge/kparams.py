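"""Data-driven rules for the ridge biasing parameter k.

Sixteen estimators of the ridge parameter, all computed from the
canonical-form quantities of a quasi-likelihood fit: the rotated
coefficients alpha_j, the eigenvalues lambda_j of F = X'WX, and the
Pearson dispersion gamma.  Rules k1-k3 are the classical
Hoerl-Kennard-type choices, k4-k9 adapt shrinkage rules developed for
gamma ridge regression, and k10-k16 are shrinkage rules specific to
the quasi-Poisson ridge estimator.

All rules are permutation-invariant in j and return strictly positive
values on valid input.  The rules that divide by alpha_j^2 (k3, k10,
k11, k13, k14) require every alpha_j to be nonzero.

Note on k11: the default implements sum_j r_j * (2 + r_j^2) with
r_j = gamma/alpha_j^2, i.e. the formula exactly as published for this
estimator.  The related literature rule with a square root,
sum_j r_j * (1 + sqrt(1 + r_j^2)), is available as the opt-in variant
``k11_sqrt`` but is never used by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .quasipoisson import CountDataset, QLEFit, fit_qle
from .ridge import EigenSystem, RidgeFit, eigen_decompose, ridge_coefficients, ridge_moments

RULE_NAMES = tuple(f"k{i}" for i in range(1, 17))

# Rules whose formula divides by alpha_j^2 directly.
_NEEDS_NONZERO_ALPHA = {"k3", "k10", "k11", "k11_sqrt", "k13", "k14"}


@dataclass(frozen=True)
class KRuleInput:
    """Canonical-form inputs consumed by every k-rule."""

    alpha: np.ndarray    # rotated coefficients, length p+1
    lambdas: np.ndarray  # eigenvalues of F, length p+1
    gamma: float         # Pearson dispersion estimate
    p: int               # number of non-intercept regressors

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        lambdas = np.asarray(self.lambdas, dtype=float)
        if alpha.shape != (self.p + 1,) or lambdas.shape != (self.p + 1,):
            raise ValidationError(
                f"alpha and lambdas must both have length p+1 = {self.p + 1}"
            )
        if self.gamma <= 0:
            raise ValidationError("gamma must be strictly positive")
        if np.any(lambdas <= 0):
            raise ValidationError("all eigenvalues must be strictly positive")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "lambdas", lambdas)

    @classmethod
    def from_fit(cls, fit: QLEFit, eig: EigenSystem) -> "KRuleInput":
        return cls(
            alpha=eig.alpha,
            lambdas=eig.lambdas,
            gamma=fit.gamma_hat,
            p=len(fit.beta) - 1,
        )


def _k1(a2, lam, g, q):
    return g / np.sum(a2)


def _k2(a2, lam, g, q):
    return q * g / np.sum(a2)


def _k3(a2, lam, g, q):
    return np.max(g / a2)


def _k4(a2, lam, g, q):
    return (g / q) * np.sum(1.0 / (2.0 * a2 + np.max(g / lam)))


def _k5(a2, lam, g, q):
    return np.median(g / (2.0 * np.min(a2) + g / lam))


def _k6(a2, lam, g, q):
    return (g / q) * np.sum(1.0 / (2.0 * a2 + g / lam))


def _k7(a2, lam, g, q):
    return np.median(g / (2.0 * a2 + g / lam))


def _k8(a2, lam, g, q):
    return (1.0 / g) * np.max(g / (2.0 * a2 + np.max(g / lam)))


def _k9(a2, lam, g, q):
    return np.prod((g / (2.0 * a2 + g / lam)) ** (1.0 / q))


def _k10(a2, lam, g, q):
    return np.min(g * lam / a2)


def _k11(a2, lam, g, q):
    r = g / a2
    return np.sum(r * (2.0 + r**2))


def _k11_sqrt(a2, lam, g, q):
    r = g / a2
    return np.sum(r * (1.0 + np.sqrt(1.0 + r**2)))


def _k12(a2, lam, g, q):
    return np.sum(lam * g / (g + lam * a2))


def _k13(a2, lam, g, q):
    return 1.0 / np.max(a2)


def _k14(a2, lam, g, q):
    return np.sum(1.0 / a2)


def _k15(a2, lam, g, q):
    return np.sum(lam / (1.0 + 2.0 * lam * a2))


def _k16(a2, lam, g, q):
    return q * np.sum(g / (2.0 * a2 + g / lam))


_RULES = {
    "k1": _k1, "k2": _k2, "k3": _k3, "k4": _k4, "k5": _k5, "k6": _k6,
    "k7": _k7, "k8": _k8, "k9": _k9, "k10": _k10, "k11": _k11,
    "k11_sqrt": _k11_sqrt, "k12": _k12, "k13": _k13, "k14": _k14,
    "k15": _k15, "k16": _k16,
}


def ridge_k(rule: str, inp: KRuleInput) -> float:
    """Evaluate one biasing-parameter rule.

    Parameters
    ----------
    rule : str
        One of "k1" ... "k16" (or the opt-in variant "k11_sqrt").
    inp : KRuleInput
        Canonical-form quantities of the fit.
    """
    if rule not in _RULES:
        raise ValidationError(
            f"unknown ridge-parameter rule {rule!r}; expected one of {RULE_NAMES}"
        )
    if rule in _NEEDS_NONZERO_ALPHA and np.any(inp.alpha == 0):
        raise ValidationError(
            f"rule {rule} divides by alpha_j^2 but some alpha_j is zero"
        )
    a2 = inp.alpha**2
    value = float(_RULES[rule](a2, inp.lambdas, inp.gamma, inp.p + 1))
    return value


def all_ridge_k(inp: KRuleInput) -> dict:
    """All sixteen rule values as an ordered dict name -> k."""
    return {name: ridge_k(name, inp) for name in RULE_NAMES}


def fit_qprre(
    data: CountDataset,
    rule: str | None = None,
    k: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    qle: QLEFit | None = None,
) -> RidgeFit:
    """End-to-end quasi-Poisson ridge fit.

    Pipeline: IWLS quasi-likelihood fit -> eigen-decomposition of F ->
    Pearson dispersion -> biasing parameter (rule or fixed ``k``) ->
    ridge coefficients and their exact moments.  The bias is evaluated
    at the QLE coefficients.

    Exactly one of ``rule`` and ``k`` must be given.  A fixed k = 0
    reproduces the quasi-likelihood fit.  A pre-computed ``qle`` fit
    may be passed to avoid refitting.
    """
    if (rule is None) == (k is None):
        raise ValidationError("specify exactly one of rule= or k=")
    fit = qle if qle is not None else fit_qle(data, tol=tol, max_iter=max_iter)
    eig = eigen_decompose(fit.F, fit.beta)
    if rule is not None:
        inp = KRuleInput.from_fit(fit, eig)
        k_value = ridge_k(rule, inp)
        rule_name = rule
    else:
        if k < 0:
            raise ValidationError("fixed k must be non-negative")
        k_value = float(k)
        rule_name = "fixed"
    beta_k = ridge_coefficients(fit.F, fit.beta, k_value)
    bias, cov, mmse, m1, m2, mse = ridge_moments(
        eig, fit.gamma_hat, k_value, fit.beta
    )
    mu_k = np.exp(np.clip(data.X @ beta_k, -700, 700))
    return RidgeFit(
        k=k_value,
        rule=rule_name,
        beta_k=beta_k,
        bias=bias,
        cov=cov,
        mmse=mmse,
        m1=m1,
        m2=m2,
        mse=mse,
        mu=mu_k,
        gamma_hat=fit.gamma_hat,
        names=data.names,
    )
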