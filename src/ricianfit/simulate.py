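"""Synthetic Rician-distributed IVIM data.

The generator reproduces the simulation design used to study loss-function
bias: ground-truth parameters on a full factorial grid of equidistant levels
(default 10 per parameter over the physiological ranges, 10^4 combinations),
a fixed number of noisy instantiations per combination (default 20, giving
200,000 voxels), and Rician noise formed exactly as in magnitude
reconstruction — independent zero-mean Gaussians of std sigma added to the
real and imaginary channels before taking the magnitude.

Noise levels are set through SNR = 1/sigma at unit b=0 signal; the standard
study SNRs are {30, 20, 10, 7.5, 5}, varied through sigma only.

One parent seed spawns independent child streams per split, so resizing one
split never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ivim import (
    DEFAULT_PARAM_RANGES,
    PARAM_NAMES,
    AcquisitionProtocol,
    ivim_signal,
)
from .rician import NoiseSpec

__all__ = [
    "SignalBatch",
    "make_parameter_grid",
    "add_rician_noise",
    "build_dataset",
    "STUDY_SNRS",
]

#: SNRs at which the loss comparison study simulates data
STUDY_SNRS = (30.0, 20.0, 10.0, 7.5, 5.0)


@dataclass
class SignalBatch:
    """A batch of magnitude voxels with protocol and optional ground truth."""

    M: np.ndarray
    protocol: AcquisitionProtocol
    truth: pd.DataFrame | None = None
    sigma_true: NoiseSpec | None = None
    seed: int | None = None
    combo_id: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        if self.M.shape[1] != self.protocol.n_measurements:
            raise ValueError(
                f"{self.M.shape[1]} signal columns but protocol has "
                f"{self.protocol.n_measurements} b-values"
            )
        if self.M.size and np.any(self.M <= 0):
            raise ValueError("magnitudes must be strictly positive")
        if self.truth is not None and len(self.truth) != self.M.shape[0]:
            raise ValueError("truth table must have one row per voxel")

    @property
    def n_voxels(self) -> int:
        return self.M.shape[0]


def make_parameter_grid(
    ranges: dict | None = None, n_levels: int = 10
) -> pd.DataFrame:
    """Full factorial grid of equidistant parameter levels.

    Each parameter gets ``n_levels`` equally spaced values including both
    endpoints; the grid is their Cartesian product (n_levels^4 rows for IVIM),
    ordered with Dt varying slowest.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2 (endpoints are included)")
    ranges = dict(DEFAULT_PARAM_RANGES if ranges is None else ranges)
    levels = {}
    for name in PARAM_NAMES:
        lo, hi = ranges[name]
        if not lo < hi:
            raise ValueError(f"invalid range for {name}: [{lo}, {hi}]")
        levels[name] = np.linspace(lo, hi, n_levels)
    mesh = np.meshgrid(*(levels[n] for n in PARAM_NAMES), indexing="ij")
    grid = pd.DataFrame({n: m.ravel() for n, m in zip(PARAM_NAMES, mesh)})
    grid.index.name = "combo_id"
    return grid


def add_rician_noise(A, sigma: float, seed: int) -> np.ndarray:
    """Corrupt noise-free signals with Rician noise.

    M = sqrt((A + n_R)^2 + n_I^2), n_R, n_I ~ N(0, sigma^2) independent —
    complex Gaussian noise followed by magnitude computation. Bit-reproducible
    for a fixed seed.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("noise-free signals must be nonnegative")
    rng = np.random.default_rng(seed)
    n_r = rng.normal(0.0, sigma, size=A.shape)
    n_i = rng.normal(0.0, sigma, size=A.shape)
    return np.sqrt((A + n_r) ** 2 + n_i**2)


def _noisy_batch(grid, protocol, sigma, reps, rng_seed):
    pos = np.repeat(np.arange(len(grid)), reps)
    combo_id = grid.index.to_numpy()[pos]
    truth = grid.iloc[pos].reset_index(drop=True)
    truth["combo_id"] = combo_id
    A = ivim_signal(truth[list(PARAM_NAMES)].to_numpy(), protocol)
    M = add_rician_noise(A, sigma, rng_seed)
    return M, truth, combo_id


def build_dataset(
    grid: pd.DataFrame,
    protocol: AcquisitionProtocol,
    sigma: float,
    reps_per_combo: int = 20,
    seed: int = 0,
    n_validation: int = 1000,
) -> tuple:
    """Simulate a training batch plus a validation batch.

    ``reps_per_combo`` noisy instantiations are drawn for every grid row
    (defaults reproduce 10^4 combinations x 20 = 200,000 training voxels).
    Validation voxels are grid combinations sampled uniformly with fresh
    noise from an independently spawned stream.

    Returns
    -------
    (train, val) : SignalBatch pair; ``val`` is None when n_validation == 0.
    """
    if reps_per_combo < 1:
        raise ValueError("reps_per_combo must be >= 1")
    ss_train, ss_val = np.random.SeedSequence(seed).spawn(2)

    M, truth, combo_id = _noisy_batch(
        grid, protocol, sigma, reps_per_combo, ss_train
    )
    train = SignalBatch(
        M=M, protocol=protocol, truth=truth,
        sigma_true=NoiseSpec(sigma), seed=seed, combo_id=combo_id,
    )

    val = None
    if n_validation > 0:
        rng = np.random.default_rng(ss_val)
        rows = rng.integers(0, len(grid), size=n_validation)
        Mv, vtruth, vcombo = _noisy_batch(grid.iloc[rows], protocol, sigma, 1, rng)
        val = SignalBatch(
            M=Mv, protocol=protocol, truth=vtruth,
            sigma_true=NoiseSpec(sigma), seed=seed, combo_id=vcombo,
        )
    return train, val
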