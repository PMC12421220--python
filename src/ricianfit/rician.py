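"""Rician distribution math and the two self-supervised training losses.

A magnitude voxel M = sqrt((A + n_R)^2 + n_I^2) with n_R, n_I ~ N(0, sigma^2)
follows a Rician distribution with location parameter A (the noise-free
signal) and scale sigma (the per-channel noise standard deviation). SNR is
defined as 1/sigma referenced to a unit b=0 signal.

Two amortised batch losses are provided:

* ``mse_loss`` — mean squared error between measured and predicted signals;
  its minimiser is the voxel-wise least-squares estimate, biased for Rician
  data because E[M] > A.
* ``nlr_loss`` — negative log Rician likelihood, the maximum-likelihood
  objective, evaluated through the exponentially scaled Bessel function so it
  is stable at any SNR.

Both losses also expose analytic gradients with respect to the predicted
signal, which the network training loop backpropagates through the forward
model. All accumulation is in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e

from .bessel import bessel_i1i0_ratio, log_i0

__all__ = [
    "NoiseSpec",
    "LossValue",
    "rician_logpdf",
    "expected_magnitude",
    "nlr_loss",
    "nlr_loss_grad",
    "mse_loss",
    "mse_loss_grad",
    "A_FLOOR",
]

# floor applied to predicted signals inside the losses only, so transiently
# nonpositive predictions cannot leave the Bessel domain
A_FLOOR = 1e-12


@dataclass(frozen=True)
class NoiseSpec:
    """Scalar noise level: per-channel Gaussian std sigma; SNR = 1/sigma."""

    sigma: float

    def __post_init__(self):
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be a positive finite real, got {self.sigma}")

    @property
    def snr(self) -> float:
        return 1.0 / self.sigma

    @classmethod
    def from_snr(cls, snr: float) -> "NoiseSpec":
        if snr <= 0:
            raise ValueError("snr must be positive")
        return cls(sigma=1.0 / snr)


@dataclass(frozen=True)
class LossValue:
    """Amortised batch loss with optional per-voxel contributions."""

    value: float
    per_voxel: np.ndarray | None = field(default=None, repr=False)

    def __float__(self) -> float:
        return self.value


def _check_sigma(sigma):
    if not np.isscalar(sigma) or sigma <= 0 or not np.isfinite(sigma):
        raise ValueError(f"sigma must be a positive finite scalar, got {sigma!r}")


def rician_logpdf(M, A, sigma):
    """Log density of the Rician distribution, elementwise.

    log p(M | A, sigma) = log(M/sigma^2) - (M^2 + A^2)/(2 sigma^2)
                          + log I0(M*A/sigma^2)

    ``M`` must be positive (magnitude data), ``A`` nonnegative. At A = 0 the
    density reduces to the Rayleigh distribution.
    """
    _check_sigma(sigma)
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(M <= 0):
        raise ValueError("rician_logpdf requires M > 0 (magnitude data)")
    if np.any(A < 0):
        raise ValueError("rician_logpdf requires A >= 0")
    s2 = sigma * sigma
    out = np.log(M / s2) - (M * M + A * A) / (2.0 * s2) + log_i0(M * A / s2)
    return out if np.ndim(out) else float(out)


def expected_magnitude(A, sigma):
    """Expected Rician magnitude E[M | A, sigma].

    E[M] = sigma * sqrt(pi/2) * L_{1/2}(-A^2 / (2 sigma^2)) where L_{1/2} is
    the order-1/2 Laguerre polynomial. Evaluated through the stable identity

        L_{1/2}(-t) = (1 + t) * I0e(t/2) + t * I1e(t/2),   t = A^2/(2 sigma^2)

    using exponentially scaled Bessels, so it neither overflows nor loses the
    high-SNR limit E[M] -> A. Strictly greater than A for all A >= 0.
    """
    _check_sigma(sigma)
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("expected_magnitude requires A >= 0")
    t = A * A / (2.0 * sigma * sigma)
    laguerre_half = (1.0 + t) * i0e(t / 2.0) + t * i1e(t / 2.0)
    out = sigma * np.sqrt(np.pi / 2.0) * laguerre_half
    return out if np.ndim(out) else float(out)


def _conformable(M, A_hat):
    M = np.atleast_2d(np.asarray(M, dtype=float))
    A_hat = np.atleast_2d(np.asarray(A_hat, dtype=float))
    if M.shape != A_hat.shape:
        raise ValueError(f"shape mismatch: M {M.shape} vs A_hat {A_hat.shape}")
    return M, A_hat


def nlr_loss(M, A_hat, sigma) -> LossValue:
    """Negative log Rician likelihood loss over a batch.

    value = (1/N) * sum_j [ - sum_i log p(M_ij | A_hat_ij, sigma) ]

    The per-voxel negative log likelihood is summed over the Nz measurements
    of each voxel and averaged over the N voxels of the batch. Predictions
    are floored at a tiny positive value so the Bessel argument stays in
    domain if an unconstrained optimiser wanders negative.
    """
    _check_sigma(sigma)
    M, A_hat = _conformable(M, A_hat)
    if np.any(M <= 0):
        raise ValueError("nlr_loss requires positive magnitudes M")
    A = np.maximum(A_hat, A_FLOOR)
    s2 = sigma * sigma
    ll = np.log(M / s2) - (M * M + A * A) / (2.0 * s2) + log_i0(M * A / s2)
    per_voxel = -np.sum(ll, axis=1)
    return LossValue(value=float(np.mean(per_voxel)), per_voxel=per_voxel)


def nlr_loss_grad(M, A_hat, sigma):
    """Gradient of ``nlr_loss().value`` with respect to A_hat.

    d/dA [-log p] = (A - M * I1/I0(M*A/sigma^2)) / sigma^2, divided by the
    batch size N from the outer mean. Bounded ratio I1/I0 in [0,1) keeps the
    gradient finite on the whole valid domain.
    """
    _check_sigma(sigma)
    M, A_hat = _conformable(M, A_hat)
    A = np.maximum(A_hat, A_FLOOR)
    s2 = sigma * sigma
    ratio = bessel_i1i0_ratio(M * A / s2)
    grad = (A - M * ratio) / s2 / M.shape[0]
    grad[A_hat < A_FLOOR] = 0.0  # flat below the floor
    return grad


def mse_loss(M, A_hat) -> LossValue:
    """Mean squared error loss: (1/N) sum_j (1/Nz) sum_i (M_ij - A_hat_ij)^2."""
    M, A_hat = _conformable(M, A_hat)
    per_voxel = np.mean((M - A_hat) ** 2, axis=1)
    return LossValue(value=float(np.mean(per_voxel)), per_voxel=per_voxel)


def mse_loss_grad(M, A_hat):
    """Gradient of ``mse_loss().value`` with respect to A_hat."""
    M, A_hat = _conformable(M, A_hat)
    return 2.0 * (A_hat - M) / M.size
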