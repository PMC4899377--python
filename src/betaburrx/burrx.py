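"""Burr type X (generalized Rayleigh) baseline distribution.

CDF: F(x) = (1 - exp(-(lam*x)^2))**theta, x >= 0, lam, theta > 0.
The density is the derivative of the CDF,

    f(x) = 2*theta*lam^2*x * exp(-(lam*x)^2) * (1 - exp(-(lam*x)^2))**(theta-1).

theta = 1 gives the Rayleigh law; lam = 1 the one-parameter Burr X.
All ``1 - exp(-z)`` factors go through expm1/log1p so both tails keep
full relative precision.
"""

from __future__ import annotations

import numpy as np

from ._stable import log1mexp
from .params import BurrXParams

__all__ = ["burrx_cdf", "burrx_logpdf", "burrx_pdf"]


def _check_nonneg(x: np.ndarray) -> None:
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")


def _check_pos(x: np.ndarray) -> None:
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive")


def burrx_cdf(x, p: BurrXParams):
    """CDF of the Burr X law at ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    _check_nonneg(x)
    z = (p.lam * x) ** 2
    # log F = theta * log(1 - e^{-z}); -inf at x = 0 maps to F = 0
    log_u = log1mexp(z)
    out = np.exp(p.theta * log_u)
    return out if out.ndim else float(out)


def burrx_logpdf(x, p: BurrXParams):
    """log-density of the Burr X law; domain error for x <= 0."""
    x = np.asarray(x, dtype=float)
    _check_pos(x)
    z = (p.lam * x) ** 2
    log_u = log1mexp(z)
    out = (
        np.log(2.0 * p.theta)
        + 2.0 * np.log(p.lam)
        + np.log(x)
        - z
        + (p.theta - 1.0) * log_u
    )
    return out if out.ndim else float(out)


def burrx_pdf(x, p: BurrXParams):
    """Density of the Burr X law; domain error for x <= 0."""
    out = np.exp(burrx_logpdf(x, p))
    return out if np.ndim(out) else float(out)
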