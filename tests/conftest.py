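import numpy as np
import pytest

from qpridge import CountDataset, gen_beta, gen_design, gen_response


def make_dataset(n=60, p=3, gamma=2.0, rho=0.9, seed=0):
    """Synthetic quasi-Poisson dataset with known truth."""
    rng = np.random.default_rng(seed)
    Xr = gen_design(n, p, rho, rng)
    X = np.column_stack([np.ones(n), Xr])
    beta = gen_beta(p)
    y = gen_response(X, beta, gamma, rng)
    return CountDataset(X=X, y=y), beta


@pytest.fixture
def small_data():
    data, _ = make_dataset(n=60, p=3, gamma=2.0, rho=0.9, seed=42)
    return data


def random_eigensystem(rng, dim=None):
    """Random eigenvalues, rotated coefficients and dispersion for
    property checks of the canonical-form MSE formulas."""
    dim = dim or rng.integers(2, 7)
    lambdas = np.sort(rng.uniform(0.05, 20.0, dim))[::-1]
    alpha = rng.normal(0, 1, dim)
    alpha[alpha == 0] = 0.1
    gamma = rng.uniform(0.5, 6.0)
    return lambdas, alpha, gamma
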