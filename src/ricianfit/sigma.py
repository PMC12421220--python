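"""Noise level estimation from background (signal-free) voxels.

Where the true signal is zero the Rician distribution reduces to a Rayleigh
distribution with mean sigma * sqrt(pi/2), so an unbiased estimator of the
per-channel noise standard deviation from N_BG background magnitudes is

    sigma_hat = mean(M) / sqrt(pi/2)

The study default is 10,000 background voxels. Background voxels must be
supplied explicitly (value list or volume + mask); magnitudes quantised to
exactly zero are excluded with a recorded count, since a zero magnitude is
impossible under the continuous model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rician import NoiseSpec

__all__ = ["BackgroundSample", "estimate_sigma", "DEFAULT_N_BACKGROUND"]

logger = logging.getLogger(__name__)

#: background sample size used in the study
DEFAULT_N_BACKGROUND = 10_000


@dataclass(frozen=True)
class BackgroundSample:
    """Magnitudes drawn from a signal-free region."""

    values: np.ndarray
    n_excluded_zeros: int = 0

    @classmethod
    def from_values(cls, values) -> "BackgroundSample":
        v = np.asarray(values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("background sample is empty")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("background magnitudes must be finite and nonnegative")
        zeros = int(np.sum(v == 0))
        if zeros:
            logger.info("excluding %d zero-valued background voxels", zeros)
            v = v[v > 0]
            if v.size == 0:
                raise ValueError("all background voxels are zero-valued")
        return cls(values=v, n_excluded_zeros=zeros)

    @classmethod
    def from_volume(cls, volume, mask) -> "BackgroundSample":
        volume = np.asarray(volume, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != volume.shape[: mask.ndim]:
            raise ValueError("mask shape does not match volume")
        return cls.from_values(volume[mask])

    @property
    def n(self) -> int:
        return int(self.values.size)


def estimate_sigma(bg) -> NoiseSpec:
    """Rayleigh-mean estimate of sigma from a background sample.

    Accepts a :class:`BackgroundSample` or anything array-like. Returns a
    :class:`~ricianfit.rician.NoiseSpec` (sigma and derived SNR).
    """
    if not isinstance(bg, BackgroundSample):
        bg = BackgroundSample.from_values(bg)
    sigma_hat = float(np.mean(bg.values) / np.sqrt(np.pi / 2.0))
    return NoiseSpec(sigma=sigma_hat)
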