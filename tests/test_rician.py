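"""Rician distribution math and the NLR / MSE losses."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import hyp1f1

import ricianfit as rf
from ricianfit.rician import mse_loss_grad, nlr_loss_grad


class TestLogPdf:
    def test_rayleigh_special_case(self):
        # A = 0 collapses the density to Rayleigh: log(1) - 1/2 + 0
        assert rf.rician_logpdf(1.0, 0.0, 1.0) == pytest.approx(-0.5)

    @pytest.mark.parametrize("A", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("sigma", [0.05, 0.2, 1.0])
    def test_density_normalizes(self, A, sigma):
        val, err = quad(lambda m: np.exp(rf.rician_logpdf(m, A, sigma)),
                        1e-12, A + 60 * sigma, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_near_location_at_high_snr(self):
        # Gaussian limit: the density peaks within 0.1 sigma of A
        A, sigma = 5.0, 0.1  # A/sigma = 50
        res = minimize_scalar(lambda m: -rf.rician_logpdf(m, A, sigma),
                              bounds=(A - sigma, A + sigma), method="bounded")
        assert abs(res.x - A) < 0.1 * sigma

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rf.rician_logpdf(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            rf.rician_logpdf(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            rf.rician_logpdf(1.0, 1.0, 0.0)


class TestExpectedMagnitude:
    def test_rayleigh_mean(self):
        assert rf.expected_magnitude(0.0, 1.0) == pytest.approx(
            np.sqrt(np.pi / 2), rel=1e-12)

    def test_matches_laguerre_via_hypergeometric(self):
        # independent route: L_{1/2}(x) = 1F1(-1/2, 1, x)
        A = np.linspace(0.0, 5.0, 21)
        sigma = 0.4
        oracle = sigma * np.sqrt(np.pi / 2) * hyp1f1(
            -0.5, 1.0, -A**2 / (2 * sigma**2))
        assert rf.expected_magnitude(A, sigma) == pytest.approx(oracle,
                                                                rel=1e-9)

    def test_monte_carlo_oracle(self):
        A, sigma, n = 1.0, 0.5, 10**6
        rng = np.random.default_rng(123)
        m = np.sqrt((A + rng.normal(0, sigma, n)) ** 2
                    + rng.normal(0, sigma, n) ** 2)
        se = m.std(ddof=1) / np.sqrt(n)
        assert abs(rf.expected_magnitude(A, sigma) - m.mean()) < 3 * se

    def test_exceeds_location_and_converges_at_high_snr(self):
        A = np.linspace(0.0, 10.0, 50)
        em = rf.expected_magnitude(A, 0.1)
        assert np.all(em > A)
        assert abs(rf.expected_magnitude(10.0, 0.1) - 10.0) < 1e-3

    def test_relative_excess_shrinks_monotonically_with_snr(self):
        A = np.linspace(0.5, 20.0, 40)
        ratio = rf.expected_magnitude(A, 1.0) / A
        assert np.all(np.diff(ratio) < 0)


class TestNlrLoss:
    def test_single_measurement_matches_logpdf(self):
        lv = rf.nlr_loss(np.array([[1.0]]), np.array([[0.0]]), 1.0)
        assert lv.value == pytest.approx(0.5)
        assert lv.per_voxel.shape == (1,)

    def test_value_is_mean_of_per_voxel(self):
        rng = np.random.default_rng(5)
        M = np.abs(rng.normal(1, 0.2, (40, 10))) + 0.01
        A = np.abs(rng.normal(1, 0.2, (40, 10)))
        lv = rf.nlr_loss(M, A, 0.1)
        assert lv.value == pytest.approx(lv.per_voxel.mean())

    def test_invariant_to_measurement_and_voxel_ordering(self):
        rng = np.random.default_rng(6)
        M = np.abs(rng.normal(1, 0.2, (20, 10))) + 0.01
        A = np.abs(rng.normal(1, 0.2, (20, 10)))
        base = rf.nlr_loss(M, A, 0.1).value
        pv = rng.permutation(20)
        assert rf.nlr_loss(M[pv], A[pv], 0.1).value == pytest.approx(base)
        pm = rng.permutation(10)
        assert rf.nlr_loss(M[:, pm], A[:, pm], 0.1).value == pytest.approx(base)

    @pytest.mark.parametrize("snr", [0.5, 2.5, 10.0, 20.0, 40.0])
    def test_finite_loss_and_gradient_across_snr(self, snr, protocol):
        sigma = 1.0 / snr
        grid = rf.make_parameter_grid(n_levels=3)
        batch, _ = rf.build_dataset(grid, protocol, sigma, reps_per_combo=2,
                                    seed=9, n_validation=0)
        A = rf.ivim_signal(batch.truth[list(rf.PARAM_NAMES)].to_numpy(),
                           protocol)
        lv = rf.nlr_loss(batch.M, A, sigma)
        g = nlr_loss_grad(batch.M, A, sigma)
        assert np.isfinite(lv.value)
        assert np.isfinite(lv.per_voxel).all()
        assert np.isfinite(g).all()

    def test_scalar_minimizer_matches_grid_search_oracle(self):
        # one voxel, Nz = 10; constant prediction A; brute-force grid vs
        # gradient descent on the loss must land in the same place
        rng = np.random.default_rng(11)
        sigma = 0.2
        M = np.abs(1.0 + rng.normal(0, sigma, (1, 10)))
        grid = np.linspace(0.0, 2 * M.max(), 10**4)
        losses = [rf.nlr_loss(M, np.full((1, 10), a), sigma).value
                  for a in grid]
        a_grid = grid[int(np.argmin(losses))]
        # plain gradient descent on the same objective
        a, lr = float(M.mean()), 5e-3
        for _ in range(4000):
            g = nlr_loss_grad(M, np.full((1, 10), a), sigma).sum()
            a -= lr * g
        step = grid[1] - grid[0]
        assert abs(a - a_grid) <= step

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        M = np.abs(rng.normal(1, 0.3, (4, 6))) + 0.05
        A = np.abs(rng.normal(1, 0.3, (4, 6))) + 0.05
        g = nlr_loss_grad(M, A, 0.15)
        eps = 1e-7
        for idx in [(0, 0), (2, 3), (3, 5)]:
            Ap, Am = A.copy(), A.copy()
            Ap[idx] += eps
            Am[idx] -= eps
            fd = (rf.nlr_loss(M, Ap, 0.15).value
                  - rf.nlr_loss(M, Am, 0.15).value) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-5)

    def test_shape_and_sigma_validation(self):
        with pytest.raises(ValueError):
            rf.nlr_loss(np.ones((2, 3)), np.ones((2, 4)), 1.0)
        with pytest.raises(ValueError):
            rf.nlr_loss(np.ones((2, 3)), np.ones((2, 3)), -1.0)


class TestMseLoss:
    def test_identity_and_hand_value(self):
        M = np.array([[1.0, 0.0]])
        assert rf.mse_loss(M, M).value == 0.0
        assert rf.mse_loss(M, np.zeros((1, 2))).value == pytest.approx(0.5)

    def test_constant_minimizer_is_sample_mean(self):
        rng = np.random.default_rng(8)
        M = rng.normal(1, 0.3, (1, 10))
        mean = M.mean()
        grid = np.linspace(M.min(), M.max(), 2001)
        losses = [rf.mse_loss(M, np.full((1, 10), a)).value for a in grid]
        assert grid[int(np.argmin(losses))] == pytest.approx(
            mean, abs=grid[1] - grid[0])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        M = rng.normal(1, 0.3, (3, 5))
        A = rng.normal(1, 0.3, (3, 5))
        g = mse_loss_grad(M, A)
        eps = 1e-7
        Ap = A.copy()
        Ap[1, 2] += eps
        fd = (rf.mse_loss(M, Ap).value - rf.mse_loss(M, A).value) / eps
        assert g[1, 2] == pytest.approx(fd, rel=1e-5)


class TestNoiseSpec:
    def test_snr_is_reciprocal_sigma(self):
        spec = rf.NoiseSpec(sigma=0.1)
        assert spec.snr * spec.sigma == pytest.approx(1.0)
        assert rf.NoiseSpec.from_snr(40.0).sigma == pytest.approx(0.025)

    def test_invalid_sigma_rejected(self):
        for bad in (0.0, -1.0, np.nan):
            with pytest.raises(ValueError):
                rf.NoiseSpec(sigma=bad)
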