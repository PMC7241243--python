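"""Structured correlation matrices, vine sampling, and Gaussian draws."""

import numpy as np
import pytest

from diffconn import (
    AssociationError,
    association_matrix,
    average_abs_correlation,
    beta_shape_from_moments,
    calibrate_mu,
    hub_correlation,
    hub_matrix,
    perturb_hardin,
    sample_gaussian,
    toeplitz_matrix,
    vine_matrix,
)


def _assert_valid_correlation(m, tol=1e-10):
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 1.0)
    assert np.linalg.eigvalsh(m)[0] > tol


class TestToeplitz:
    def test_rho_zero_identity(self):
        assert np.array_equal(toeplitz_matrix(5, 0.0).matrix, np.eye(5))

    def test_entries_exact(self):
        m = toeplitz_matrix(4, 0.5).matrix
        assert np.array_equal(m[0], [1.0, 0.5, 0.25, 0.125])
        p = 20
        m = toeplitz_matrix(p, 0.9).matrix
        i, j = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
        assert np.array_equal(m, 0.9 ** np.abs(i - j))

    def test_positive_definite_at_high_rho(self):
        assert toeplitz_matrix(20, 0.9).min_eigenvalue > 0

    def test_rho_one_rejected(self):
        with pytest.raises(AssociationError):
            toeplitz_matrix(4, 1.0)


class TestHardinPerturbation:
    def test_zero_noise_is_identity(self, rng):
        m = toeplitz_matrix(10, 0.5)
        assert perturb_hardin(m, 0.0, rng=rng) is m

    def test_entry_change_bounded_and_diagonal_kept(self, rng):
        base = toeplitz_matrix(20, 0.5)
        pert = perturb_hardin(base, 0.01, 2, rng)
        delta = np.abs(pert.matrix - base.matrix)
        assert delta.max() <= 2 * 0.01 + 1e-12
        assert np.array_equal(np.diag(pert.matrix), np.ones(20))

    def test_stays_positive_definite_many_seeds(self):
        base = toeplitz_matrix(20, 0.5)
        for seed in range(50):
            pert = perturb_hardin(base, 0.01, 2, np.random.default_rng(seed))
            assert pert.min_eigenvalue > 0

    def test_noise_above_min_eigenvalue_rejected(self, rng):
        base = toeplitz_matrix(20, 0.9)  # min eigenvalue ~ 0.05
        with pytest.raises(AssociationError):
            perturb_hardin(base, 0.5, rng=rng)


class TestHub:
    def test_entry_formula(self):
        # g=5, rho=0.8, rho_min=0.2, quadratic attenuation, member 3
        assert hub_correlation(3, 5, 0.8, 0.2, 2.0) == pytest.approx(
            0.8 - (1 / 3) ** 2 * 0.6, abs=1e-12)
        assert hub_correlation(2, 5, 0.8, 0.2, 2.0) == 0.8
        assert hub_correlation(5, 5, 0.8, 0.2, 2.0) == pytest.approx(0.2)

    def test_matrix_entries_exact_when_pd(self):
        m = hub_matrix((15, 5), rho=0.3, rho_min=0.0, gamma=2.0)
        _assert_valid_correlation(m.matrix)
        for i in range(2, 16):
            assert m.matrix[0, i - 1] == pytest.approx(
                hub_correlation(i, 15, 0.3), abs=1e-15)

    def test_cross_group_entries_zero(self):
        m = hub_matrix((5, 5), rho=0.4).matrix
        assert np.all(m[:5, 5:] == 0.0)

    def test_non_hub_pairs_uncorrelated(self):
        m = hub_matrix((6,), rho=0.4).matrix
        off = m[1:, 1:] - np.eye(5)
        assert np.all(off == 0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(AssociationError):
            hub_matrix((5,), rho=0.3, rho_min=0.5)
        with pytest.raises(AssociationError):
            hub_matrix((2, 5), rho=0.3)


class TestBetaMoments:
    @pytest.mark.parametrize("mu, sigma2, expected", [
        (0.5, 0.1, (0.75, 0.75)),
        (0.2, 0.01, (3.0, 12.0)),
    ])
    def test_closed_form_values(self, mu, sigma2, expected):
        a, b = beta_shape_from_moments(mu, sigma2)
        assert (a, b) == pytest.approx(expected)

    def test_round_trip_through_moments(self, rng):
        for _ in range(25):
            mu = rng.uniform(0.05, 0.95)
            s2 = rng.uniform(0.2, 0.8) * mu * (1 - mu)
            a, b = beta_shape_from_moments(mu, s2)
            assert a / (a + b) == pytest.approx(mu, abs=1e-10)
            assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(s2, abs=1e-10)

    def test_symmetry_at_half(self):
        a, b = beta_shape_from_moments(0.5, 0.05)
        assert a == pytest.approx(b)

    def test_invalid_moments_rejected(self):
        with pytest.raises(AssociationError):
            beta_shape_from_moments(0.5, 0.3)  # sigma2 >= mu(1-mu)


class TestVine:
    def test_valid_correlation_matrix_many_seeds(self):
        for seed in range(50):
            m = vine_matrix(20, 2.0, 3.0, np.random.default_rng(seed))
            _assert_valid_correlation(m.matrix)

    def test_symmetric_beta_centres_signed_mean(self, rng):
        vals = [vine_matrix(8, 2.0, 2.0, rng).matrix[np.triu_indices(8, 1)].mean()
                for _ in range(200)]
        assert abs(np.mean(vals)) < 0.05

    def test_positive_support_gives_positive_average(self, rng):
        m = vine_matrix(10, 5.0, 5.0, rng, support=(0.0, 1.0)).matrix
        assert m[np.triu_indices(10, 1)].mean() > 0.2


class TestAverageAbsCorrelation:
    def test_identity_zero(self):
        assert average_abs_correlation(np.eye(6)) == 0.0

    def test_toeplitz_hand_value(self):
        assert average_abs_correlation(toeplitz_matrix(3, 0.5)) == pytest.approx(
            (0.5 + 0.25 + 0.5) / 3, abs=1e-12)

    def test_constant_off_diagonal(self):
        m = np.full((5, 5), -0.3)
        np.fill_diagonal(m, 1.0)
        assert average_abs_correlation(m) == pytest.approx(0.3)


class TestCalibration:
    def test_round_trip_at_target(self, rng):
        mu = calibrate_mu(0.4, p=20, sigma2=0.1, rng=rng, n_matrices=40)
        a, b = beta_shape_from_moments(mu, 0.1)
        vals = [average_abs_correlation(
                    vine_matrix(20, a, b, rng, support=(0.0, 1.0)))
                for _ in range(40)]
        assert np.mean(vals) == pytest.approx(0.4, abs=0.05)

    def test_calibrated_mu_monotone_in_target(self, rng):
        mus = [calibrate_mu(t, p=20, sigma2=0.1, rng=rng, n_matrices=30)
               for t in (0.2, 0.4, 0.6, 0.8)]
        assert all(m2 >= m1 - 1e-6 for m1, m2 in zip(mus, mus[1:]))


class TestGaussianSampling:
    def test_null_sampling_bound(self, rng):
        X = sample_gaussian(toeplitz_matrix(5, 0.0), 5000, rng)
        A = association_matrix(X).weights
        off = np.abs(A[np.triu_indices(5, 1)])
        assert off.max() < 0.06

    def test_recovers_toeplitz_entries(self, rng):
        X = sample_gaussian(toeplitz_matrix(5, 0.6), 5000, rng)
        A = association_matrix(X).weights
        assert np.abs(A - toeplitz_matrix(5, 0.6).matrix).max() < 0.05

    def test_output_shape_and_determinism(self):
        m = toeplitz_matrix(4, 0.3)
        a = sample_gaussian(m, 7, np.random.default_rng(3))
        b = sample_gaussian(m, 7, np.random.default_rng(3))
        assert a.shape == (7, 4)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_lag_one_parameter_recovery(self, rho, rng):
        X = sample_gaussian(toeplitz_matrix(20, rho), 2000, rng)
        A = association_matrix(X).weights
        lag1 = np.array([A[i, i + 1] for i in range(19)]).mean()
        assert lag1 == pytest.approx(rho, abs=0.05)
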