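"""Parameter and state containers for the replicative-ageing model.

All quantities are dimensionless unless noted otherwise.  The model tracks a
single cell through two coupled pools, intact proteins ``P`` and damaged
proteins ``D``, each expressed as a fraction of its threshold: division is
triggered at ``P = 1`` and death at ``D = 1``.  Time ``tau`` is measured in
units of the inverse growth rate (``tau = mu * t``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class InvalidStateError(ValueError):
    """A cell state or parameter set violates a model invariant."""


class InfeasibleRetentionError(ValueError):
    """Requested damage retention would leave the mother with negative P.

    The analytic retention bound re <= (2s-1) / ((1-s) * Q * D) marks the
    largest feasible retention coefficient for the damage load at division.
    """


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise InvalidStateError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class RateParameters:
    """Dimensionless kinetic parameters of the continuous dynamics.

    Parameters
    ----------
    g
        Growth factor; the growth term reads ``P * (g - D)``.  Must exceed 1
        so a damage-free cell grows.
    k1
        Damage formation rate as a fraction of the growth rate mu.
    k2
        Damage repair rate as a fraction of mu.
    Q
        Damage resilience quotient, the ratio of the death threshold to the
        division threshold (``D_death / P_div``).  Interpretable as the
        relative size increase of an old cell over a newborn one; measured
        values for budding yeast cluster around 2.5-3.0.
    """

    g: float
    k1: float
    k2: float
    Q: float

    def __post_init__(self) -> None:
        for name in ("g", "k1", "k2", "Q"):
            _require_finite(name, getattr(self, name))
        if self.g <= 1:
            raise InvalidStateError(f"g must be > 1, got {self.g}")
        if self.k1 < 0 or self.k2 < 0:
            raise InvalidStateError("k1 and k2 must be non-negative")
        if self.Q <= 0:
            raise InvalidStateError(f"Q must be positive, got {self.Q}")

    def replace(self, **kwargs: float) -> "RateParameters":
        params = {"g": self.g, "k1": self.k1, "k2": self.k2, "Q": self.Q}
        params.update(kwargs)
        return RateParameters(**params)


@dataclass(frozen=True)
class DivisionParameters:
    """Parameters of the discrete division map.

    ``s`` is the fraction of total content the mother keeps (0.5 symmetric,
    budding yeast divides with s near 0.64); ``re`` is the fraction of damage
    retained by the mother over and above its size share.
    """

    s: float
    re: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("s", self.s)
        _require_finite("re", self.re)
        if not 0.5 <= self.s < 1:
            raise InvalidStateError(f"s must lie in [0.5, 1), got {self.s}")
        if not 0.0 <= self.re <= 1.0:
            raise InvalidStateError(f"re must lie in [0, 1], got {self.re}")


#: Tolerance for the state-box invariant 0 <= P, D <= 1.
_BOX_TOL = 1e-9


@dataclass(frozen=True)
class CellState:
    """Instantaneous state (P, D) of one cell at dimensionless time tau."""

    P: float
    D: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        for name in ("P", "D", "tau"):
            _require_finite(name, getattr(self, name))
        if not -_BOX_TOL <= self.P <= 1.0 + _BOX_TOL:
            raise InvalidStateError(f"P must lie in [0, 1], got {self.P}")
        if not -_BOX_TOL <= self.D <= 1.0 + _BOX_TOL:
            raise InvalidStateError(f"D must lie in [0, 1], got {self.D}")
        if self.tau < 0:
            raise InvalidStateError(f"tau must be non-negative, got {self.tau}")


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional model parameters, prior to non-dimensionalisation.

    Rates carry units of 1/h, thresholds concentration units.  If ``mu`` is
    not given it is evaluated from Monod kinetics
    ``mu = mu_max * S / (S + K_S)``, in which case ``mu_max``, ``K_S`` and
    ``S`` are all required.
    """

    k1: float
    k2: float
    g: float
    p_div: float
    d_death: float
    mu: float | None = None
    mu_max: float | None = None
    K_S: float | None = None
    S: float | None = None

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "g", "p_div", "d_death"):
            _require_finite(name, getattr(self, name))
        if self.p_div <= 0 or self.d_death <= 0:
            raise InvalidStateError("thresholds must be strictly positive")
        if self.k1 < 0 or self.k2 < 0:
            raise InvalidStateError("rates must be non-negative")
        if self.mu is None:
            if None in (self.mu_max, self.K_S, self.S):
                raise InvalidStateError(
                    "either mu, or all of (mu_max, K_S, S) must be given"
                )
        elif self.mu <= 0:
            raise InvalidStateError(f"mu must be strictly positive, got {self.mu}")

    @property
    def growth_rate(self) -> float:
        """The growth rate mu, evaluated from Monod kinetics if needed."""
        if self.mu is not None:
            return self.mu
        return self.mu_max * self.S / (self.S + self.K_S)
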