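"""Shared numerically-stable primitives."""

from __future__ import annotations

import math

import numpy as np

_LOG2 = math.log(2.0)


def log1mexp(t):
    """log(1 - exp(-t)) for t >= 0, accurate in both regimes.

    log(-expm1(-t)) for t < log 2, log1p(-exp(-t)) otherwise, keeping
    relative precision from t ~ 1e-300 up to t ~ 745 (beyond which the
    value degrades gracefully to -0.0).
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        small = np.log(-np.expm1(-np.minimum(t, _LOG2)))
        large = np.log1p(-np.exp(-np.maximum(t, _LOG2)))
    return np.where(t < _LOG2, small, large)
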