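"""Ridge estimator: canonical form, exact moments, MSE theory."""

import numpy as np
import pytest

from qpridge import (
    ValidationError,
    eigen_decompose,
    mse_derivative,
    ridge_coefficients,
    ridge_moments,
)
from qpridge.ridge import EigenSystem

from conftest import random_eigensystem


def make_eig(lambdas, alpha):
    """EigenSystem in already-diagonal coordinates (T = I)."""
    lam = np.asarray(lambdas, float)
    return EigenSystem(lambdas=lam, T=np.eye(len(lam)), alpha=np.asarray(alpha, float))


class TestEigenDecompose:
    def test_diagonal_input(self):
        F = np.diag([1.0, 5.0, 3.0])
        eig = eigen_decompose(F, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(eig.lambdas, [5.0, 3.0, 1.0])
        # columns are signed unit vectors picking out the sorted diagonal
        np.testing.assert_allclose(np.abs(eig.T).sum(axis=0), 1.0)

    def test_reconstruction_and_orthogonality(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            A = rng.normal(size=(5, 5))
            F = A @ A.T
            beta = rng.normal(size=5)
            eig = eigen_decompose(F, beta)
            recon = eig.T @ np.diag(eig.lambdas) @ eig.T.T
            assert np.max(np.abs(recon - F)) < 1e-10
            assert np.max(np.abs(eig.T.T @ eig.T - np.eye(5))) < 1e-10
            # orthogonal invariance of the coefficient norm
            assert np.sum(eig.alpha**2) == pytest.approx(np.sum(beta**2), rel=1e-12)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValidationError):
            eigen_decompose(np.array([[1.0, 2.0], [0.0, 1.0]]), np.zeros(2))

    def test_sign_convention_is_deterministic(self):
        F = np.array([[2.0, 0.4], [0.4, 1.0]])
        e1 = eigen_decompose(F, np.ones(2))
        e2 = eigen_decompose(F.copy(), np.ones(2))
        np.testing.assert_array_equal(e1.T, e2.T)
        for j in range(2):
            i = np.argmax(np.abs(e1.T[:, j]))
            assert e1.T[i, j] > 0


class TestRidgeCoefficients:
    def test_k_zero_is_identity(self):
        F = np.array([[3.0, 0.5], [0.5, 2.0]])
        beta = np.array([1.2, -0.7])
        np.testing.assert_allclose(ridge_coefficients(F, beta, 0.0), beta, atol=1e-12)

    def test_hand_value(self):
        out = ridge_coefficients(np.diag([4.0, 1.0]), np.array([1.0, 1.0]), 1.0)
        np.testing.assert_allclose(out, [0.8, 0.5], atol=1e-12)

    def test_full_shrinkage_limit(self):
        F = np.array([[3.0, 0.5], [0.5, 2.0]])
        out = ridge_coefficients(F, np.array([1.0, 1.0]), 1e12)
        assert np.linalg.norm(out) < 1e-9

    def test_negative_k_rejected(self):
        with pytest.raises(ValidationError):
            ridge_coefficients(np.eye(2), np.ones(2), -0.1)

    def test_matrix_and_canonical_forms_agree(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            A = rng.normal(size=(4, 4))
            F = A @ A.T + 0.1 * np.eye(4)
            beta = rng.normal(size=4)
            k = rng.uniform(0, 5)
            eig = eigen_decompose(F, beta)
            canonical = eig.T @ (eig.lambdas / (eig.lambdas + k) * eig.alpha)
            assert np.max(np.abs(ridge_coefficients(F, beta, k) - canonical)) < 1e-10

    def test_intercept_exclusion_option(self):
        F = np.diag([4.0, 1.0])
        out = ridge_coefficients(F, np.array([1.0, 1.0]), 1.0,
                                 penalize_intercept=False)
        np.testing.assert_allclose(out, [1.0, 0.5], atol=1e-12)


class TestRidgeMoments:
    def test_reduces_to_qle_at_k_zero(self):
        eig = make_eig([4.0, 1.0], [1.0, 1.0])
        bias, cov, mmse, m1, m2, mse = ridge_moments(eig, 2.0, 0.0, np.array([1.0, 1.0]))
        np.testing.assert_allclose(bias, 0.0, atol=1e-12)
        assert m2 == 0.0
        assert mse == pytest.approx(2.0 * (1 / 4 + 1 / 1), abs=1e-12)

    def test_hand_values(self):
        eig = make_eig([4.0, 1.0], [1.0, 1.0])
        _, _, _, m1, m2, mse = ridge_moments(eig, 2.0, 1.0, np.array([1.0, 1.0]))
        assert m1 == pytest.approx(0.82, abs=1e-12)
        assert m2 == pytest.approx(0.29, abs=1e-12)
        assert mse == pytest.approx(1.11, abs=1e-12)

    def test_trace_identity_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            lam, alpha, gamma = random_eigensystem(rng)
            dim = len(lam)
            A = rng.normal(size=(dim, dim))
            Q, _ = np.linalg.qr(A)
            eig = EigenSystem(lambdas=lam, T=Q, alpha=Q.T @ alpha)
            beta = alpha
            _, _, mmse, _, _, mse = ridge_moments(eig, gamma, rng.uniform(0, 3), beta)
            assert mse == pytest.approx(np.trace(mmse), abs=1e-10)

    def test_invariant_to_eigenvector_sign_flips(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(4, 4))
        F = A @ A.T + 0.1 * np.eye(4)
        beta = rng.normal(size=4)
        eig = eigen_decompose(F, beta)
        flipped = EigenSystem(lambdas=eig.lambdas, T=eig.T * np.array([1, -1, 1, -1]),
                              alpha=(eig.T * np.array([1, -1, 1, -1])).T @ beta)
        for k in (0.0, 0.7, 3.0):
            a = ridge_moments(eig, 1.5, k, beta)
            b = ridge_moments(flipped, 1.5, k, beta)
            np.testing.assert_allclose(a[0], b[0], atol=1e-10)  # bias
            np.testing.assert_allclose(a[2], b[2], atol=1e-10)  # mmse
            assert a[5] == pytest.approx(b[5], abs=1e-12)

    def test_mse_limit_at_large_k(self):
        eig = make_eig([4.0, 1.0], [1.0, 2.0])
        _, _, _, m1, m2, mse = ridge_moments(eig, 2.0, 1e10, np.array([1.0, 2.0]))
        assert m1 < 1e-8
        assert mse == pytest.approx(np.sum(eig.alpha**2), rel=1e-6)


class TestMseDerivative:
    def test_at_origin(self):
        eig = make_eig([4.0, 1.0], [1.0, 1.0])
        m1p, m2p, total = mse_derivative(eig, 2.0, 0.0)
        assert m2p == 0.0
        assert total == pytest.approx(-2 * 2.0 * (1 / 16 + 1), abs=1e-12)
        assert total < 0

    def test_matches_finite_difference(self):
        eig = make_eig([4.0, 1.0], [1.0, 1.0])
        gamma, k, h = 2.0, 0.5, 1e-5
        beta = eig.alpha

        def mse_at(kk):
            return ridge_moments(eig, gamma, kk, beta)[5]

        fd = (mse_at(k + h) - mse_at(k - h)) / (2 * h)
        _, _, total = mse_derivative(eig, gamma, k)
        assert total == pytest.approx(fd, abs=1e-6)

    def test_negative_below_gamma_over_alpha_max(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            lam, alpha, gamma = random_eigensystem(rng)
            eig = make_eig(lam, alpha)
            k_bound = gamma / np.max(alpha**2)
            for k in np.linspace(1e-6, k_bound * 0.999, 7):
                assert mse_derivative(eig, gamma, k)[2] < 0


class TestTheorems:
    """Monotone variance/bias components and the existence of a
    k > 0 beating the unpenalized estimator, checked numerically on
    random canonical systems."""

    def test_m1_decreases_m2_increases(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            lam, alpha, gamma = random_eigensystem(rng)
            eig = make_eig(lam, alpha)
            grid = np.linspace(0, 10 * lam[0], 40)
            m1s = [ridge_moments(eig, gamma, k, alpha)[3] for k in grid]
            m2s = [ridge_moments(eig, gamma, k, alpha)[4] for k in grid]
            assert np.all(np.diff(m1s) < 0)
            assert np.all(np.diff(m2s) > 0)

    def test_some_k_beats_k_zero(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            lam, alpha, gamma = random_eigensystem(rng)
            eig = make_eig(lam, alpha)
            mse0 = gamma * np.sum(1.0 / lam)
            grid = np.linspace(1e-4, 10 * lam[0], 200)
            best = min(ridge_moments(eig, gamma, k, alpha)[5] for k in grid)
            assert best < mse0
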