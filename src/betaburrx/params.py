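"""Parameter containers for the beta Burr type X family.

The beta Burr type X (BBX) law is built from a Burr type X baseline
with CDF ``F(x) = (1 - exp(-(lam*x)^2))**theta`` by the beta-generator
construction ``G(x) = I_{F(x)}(alpha, beta)``, where ``I`` is the
regularized incomplete beta function.  All four parameters are strictly
positive shape/scale quantities; construction is strict and never clips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BurrXParams",
    "BBXParams",
    "SeriesControl",
    "SeriesTruncationError",
]


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be a finite positive real, got {value!r}")
    return value


@dataclass(frozen=True)
class BurrXParams:
    """Burr type X baseline parameters.

    Parameters
    ----------
    lam : float
        Scale parameter (the rate inside the squared exponent), > 0.
    theta : float
        Shape parameter (the outer power on the Rayleigh CDF), > 0.
    """

    lam: float
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam", _require_positive("lam", self.lam))
        object.__setattr__(self, "theta", _require_positive("theta", self.theta))


@dataclass(frozen=True)
class BBXParams:
    """Beta Burr type X parameters (alpha, beta, lam, theta), all > 0.

    ``alpha`` and ``beta`` are the beta-generator shapes; ``lam`` and
    ``theta`` are the Burr X baseline scale and shape.  ``alpha = beta = 1``
    recovers the baseline; additionally ``theta = 1`` gives the Rayleigh
    law and ``lam = 1`` the one-parameter Burr X.
    """

    alpha: float
    beta: float
    lam: float
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _require_positive("alpha", self.alpha))
        object.__setattr__(self, "beta", _require_positive("beta", self.beta))
        object.__setattr__(self, "lam", _require_positive("lam", self.lam))
        object.__setattr__(self, "theta", _require_positive("theta", self.theta))

    @property
    def baseline(self) -> BurrXParams:
        """The Burr X baseline implied by (lam, theta)."""
        return BurrXParams(self.lam, self.theta)

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.alpha, self.beta, self.lam, self.theta)


@dataclass(frozen=True)
class SeriesControl:
    """Truncation control for the infinite-series evaluators.

    tol : absolute tolerance on the truncation remainder.
    max_terms : cap on the number of summand evaluations before the
        evaluator gives up and raises :class:`SeriesTruncationError`.
    """

    tol: float = 1e-10
    max_terms: int = 1_000_000

    def __post_init__(self) -> None:
        if not (self.tol > 0.0 and math.isfinite(self.tol)):
            raise ValueError("tol must be a finite positive real")
        if int(self.max_terms) < 1:
            raise ValueError("max_terms must be >= 1")
        object.__setattr__(self, "max_terms", int(self.max_terms))


class SeriesTruncationError(RuntimeError):
    """A series evaluator could not certify the requested tolerance.

    Raised instead of returning a silently wrong answer; the message
    recommends the corresponding closed-form/quadrature evaluator.
    """
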