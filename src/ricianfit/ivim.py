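"""IVIM bi-exponential forward model.

The intravoxel incoherent motion (IVIM) model separates tissue water
diffusion from capillary pseudo-diffusion. For diffusion weighting b the
noise-free signal is

    A(b) = S0 * ( f * exp(-b * (Dp + Dt)) + (1 - f) * exp(-b * Dt) )

with tissue diffusivity Dt [um^2/ms], pseudo-diffusion coefficient Dp
[um^2/ms], perfusion fraction f in [0, 1] and unweighted signal S0 [a.u.].

Units are fixed throughout the package: b in ms/um^2, diffusivities in
um^2/ms, so that b*D is dimensionless and Dt is of the same magnitude as S0.
Clinical protocols quote b in s/mm^2; 1 ms/um^2 = 1000 s/mm^2, and the
conversion is handled at I/O time, never inside the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "IVIMParams",
    "ivim_signal",
    "ivim_signal_jacobian",
    "PARAM_NAMES",
    "DEFAULT_B_VALUES",
    "DEFAULT_PARAM_RANGES",
]

PARAM_NAMES = ("Dt", "Dp", "f", "S0")

#: ten-b-value clinical IVIM protocol, ms/um^2 (equals 0..800 s/mm^2)
DEFAULT_B_VALUES = (0.0, 0.01, 0.02, 0.03, 0.05, 0.08, 0.1, 0.2, 0.4, 0.8)

#: physiologically plausible simulation ranges per parameter
DEFAULT_PARAM_RANGES = {
    "Dt": (0.4, 3.0),   # um^2/ms
    "Dp": (10.0, 150.0),  # um^2/ms
    "f": (0.1, 0.5),
    "S0": (0.8, 1.2),   # a.u.
}


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered diffusion weightings defining the measurement axis."""

    b_values: tuple

    def __init__(self, b_values):
        b = np.asarray(b_values, dtype=float)
        if b.ndim != 1 or b.size == 0:
            raise ValueError("b_values must be a non-empty 1-D sequence")
        if np.any(b < 0) or not np.all(np.isfinite(b)):
            raise ValueError("b_values must be finite and nonnegative")
        object.__setattr__(self, "b_values", tuple(b.tolist()))

    @property
    def n_measurements(self) -> int:
        return len(self.b_values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @classmethod
    def from_s_per_mm2(cls, b_values) -> "AcquisitionProtocol":
        """Build from clinical-convention b-values in s/mm^2."""
        return cls(np.asarray(b_values, dtype=float) / 1000.0)

    @classmethod
    def default(cls) -> "AcquisitionProtocol":
        return cls(DEFAULT_B_VALUES)


@dataclass(frozen=True)
class IVIMParams:
    """One voxel's IVIM parameters."""

    Dt: float
    Dp: float
    f: float
    S0: float

    def __post_init__(self):
        if self.Dt <= 0 or self.Dp <= 0:
            raise ValueError("diffusivities Dt and Dp must be positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("perfusion fraction f must lie in [0, 1]")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Dt, self.Dp, self.f, self.S0], dtype=float)


def _param_columns(params) -> tuple:
    """Accept IVIMParams, a 4-vector, or an (N,4) array; return column views."""
    if isinstance(params, IVIMParams):
        arr = params.as_array()[None, :]
    else:
        arr = np.atleast_2d(np.asarray(params, dtype=float))
    if arr.shape[1] != 4:
        raise ValueError("parameters must have four columns (Dt, Dp, f, S0)")
    Dt, Dp, f, S0 = (arr[:, i] for i in range(4))
    if np.any(Dt <= 0) or np.any(Dp <= 0):
        raise ValueError("diffusivities must be positive")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("perfusion fraction must lie in [0, 1]")
    if np.any(S0 <= 0):
        raise ValueError("S0 must be positive")
    return Dt[:, None], Dp[:, None], f[:, None], S0[:, None]


def ivim_signal(params, protocol: AcquisitionProtocol) -> np.ndarray:
    """Noise-free IVIM signal for each voxel and b-value.

    Parameters
    ----------
    params : IVIMParams, 4-vector or (N, 4) array in (Dt, Dp, f, S0) order.
    protocol : AcquisitionProtocol

    Returns
    -------
    ndarray
        (N, Nz) signals ordered exactly like the protocol's b-values;
        a 1-D (Nz,) vector when a single parameter set is given.
    """
    single = isinstance(params, IVIMParams) or np.asarray(params).ndim == 1
    Dt, Dp, f, S0 = _param_columns(params)
    b = protocol.as_array()[None, :]
    A = S0 * (f * np.exp(-b * (Dp + Dt)) + (1.0 - f) * np.exp(-b * Dt))
    return A[0] if single else A


def ivim_signal_jacobian(params, protocol: AcquisitionProtocol):
    """Signal and its partial derivatives with respect to (Dt, Dp, f, S0).

    Returns
    -------
    A : (N, Nz) signals
    J : (N, Nz, 4) jacobian, J[..., k] = dA/d(param_k)

    Used both by the training loop (backpropagation through the decoder) and
    by the gradient-based conventional fitter.
    """
    single = isinstance(params, IVIMParams) or np.asarray(params).ndim == 1
    Dt, Dp, f, S0 = _param_columns(params)
    b = protocol.as_array()[None, :]
    e_perf = np.exp(-b * (Dp + Dt))
    e_diff = np.exp(-b * Dt)
    A = S0 * (f * e_perf + (1.0 - f) * e_diff)
    J = np.empty(A.shape + (4,), dtype=float)
    J[..., 0] = -b * A                       # dA/dDt (both exponents carry Dt)
    J[..., 1] = -b * S0 * f * e_perf         # dA/dDp
    J[..., 2] = S0 * (e_perf - e_diff)       # dA/df
    J[..., 3] = A / S0                       # dA/dS0
    if single:
        return A[0], J[0]
    return A, J
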