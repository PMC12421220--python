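"""Numerically stable log of the modified Bessel function I0.

The Rician log-likelihood contains log I0(M*A/sigma^2), whose argument grows
with the square of the signal-to-noise ratio (x ~ SNR^2 at unit signal). I0
itself overflows double precision near x ~ 713, so the log is computed through
the exponentially scaled function I0e(x) = exp(-x) * I0(x):

    log I0(x) = log I0e(x) + x

I0e is bounded on [0, inf) (it decays like 1/sqrt(2*pi*x)), so no intermediate
quantity can overflow. The scaled function comes from SciPy's Cephes routine,
a Chebyshev-polynomial approximation accurate to near machine precision over
two input ranges (x <= 8 and x > 8).

``series_log_i0`` is an independent ground-truth construction — the power
series of I0 summed in the log domain — intended for validation only; it is
never used inside a loss.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, i0e, i1e, logsumexp

__all__ = ["log_i0", "series_log_i0", "bessel_i1i0_ratio"]


def log_i0(x):
    """log of the modified Bessel function of the first kind, order zero.

    Parameters
    ----------
    x : array_like of nonnegative floats
        Arguments, typically M * A / sigma^2 arising in the Rician
        log-likelihood; must be >= 0.

    Returns
    -------
    ndarray or float
        log I0(x), computed as ``log(i0e(x)) + x`` so that it stays finite
        for arbitrarily large x (no intermediate exceeds double range).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log_i0 requires x >= 0 (arguments arise as M*A/sigma^2)")
    out = np.log(i0e(x)) + x
    return out if out.ndim else float(out)


def series_log_i0(x, n_terms: int = 1000, strict: bool = True):
    """Ground-truth log I0 from the power series, accumulated in log domain.

    I0(x) = sum_k ((x/2)^(2k) / (k!)^2).  Each term is formed as
    2k*log(x/2) - 2*gammaln(k+1) and the sum taken with logsumexp, so the
    partial sums never overflow even when individual terms would.

    With ``strict=False`` the truncated partial sum is returned without the
    convergence check (all terms are nonnegative, so partial sums are
    monotone lower bounds of log I0).

    Raises
    ------
    ValueError
        If ``strict`` and the series has not converged within ``n_terms``
        terms (the last term is not negligible against the largest), rather
        than silently returning a truncated value.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("series_log_i0 requires x >= 0")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    scalar = x.ndim == 0
    xf = np.atleast_1d(x).ravel()

    k = np.arange(n_terms, dtype=float)
    log_terms = np.full((xf.size, n_terms), -np.inf)
    pos = xf > 0
    with np.errstate(divide="ignore"):
        log_terms[pos] = 2.0 * k * np.log(xf[pos, None] / 2.0) - 2.0 * gammaln(k + 1.0)
    log_terms[~pos, 0] = 0.0  # x = 0: only the k=0 term (=1) survives

    if strict and n_terms > 1:
        max_term = log_terms.max(axis=1)
        tail = log_terms[:, -1] - max_term
        # last term must be negligible at double precision
        if np.any(tail > -37.0):  # exp(-37) ~ 8.5e-17
            bad = float(xf[np.argmax(tail)])
            raise ValueError(
                f"series for log I0 not converged at x={bad:g} with "
                f"n_terms={n_terms}; increase n_terms"
            )
    out = logsumexp(log_terms, axis=1)
    out = out.reshape(np.atleast_1d(x).shape)
    return float(out[0]) if scalar else out


def bessel_i1i0_ratio(x):
    """I1(x)/I0(x), computed from the exponentially scaled pair.

    The ratio appears in the gradient of the Rician log-likelihood; it is
    bounded in [0, 1) so the gradient stays finite at any SNR.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("bessel_i1i0_ratio requires x >= 0")
    out = i1e(x) / i0e(x)
    return out if out.ndim else float(out)
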