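"""Continuous dynamics, division map, non-dimensionalisation and observable.

The continuous part of the model is the planar system

    dP/dtau = P (g - D) - k1 P + k2 Q D
    dD/dtau = (k1 / Q) P - k2 D

with both states confined to the unit box: P = 1 triggers division, D = 1
death.  The division map splits the cell's content between a mother (size
fraction ``s``) and a daughter (``1 - s``); the retention coefficient ``re``
moves extra damage into the mother at the cost of an equal amount of intact
protein, so total content P + Q D is conserved exactly and the mother's share
of it is exactly ``s``.

The cell-area observable is y = P + Q D: total protein content in units of
the division threshold, proportional to the cross-sectional area seen in
bright-field microscopy.
"""

from __future__ import annotations

import math

from .params import (
    CellState,
    DimensionalParameters,
    DivisionParameters,
    InfeasibleRetentionError,
    InvalidStateError,
    RateParameters,
)

__all__ = [
    "derivatives",
    "divide",
    "nondimensionalise",
    "observable",
    "retention_clamp",
]


def derivatives(
    state: CellState | tuple[float, float], rate: RateParameters
) -> tuple[float, float]:
    """Right-hand side (dP/dtau, dD/dtau) of the continuous dynamics.

    Accepts a :class:`CellState` or a bare ``(P, D)`` pair; the latter is
    useful for evaluating the field outside the unit box (the interior
    steady state sits at D = g > 1 by construction).
    """
    if isinstance(state, CellState):
        P, D = state.P, state.D
    else:
        P, D = state
    if not (math.isfinite(P) and math.isfinite(D)):
        raise InvalidStateError(f"state must be finite, got P={P}, D={D}")
    dP = P * (rate.g - D) - rate.k1 * P + rate.k2 * rate.Q * D
    dD = (rate.k1 / rate.Q) * P - rate.k2 * D
    return dP, dD


def divide(
    state: CellState,
    div: DivisionParameters,
    Q: float,
    *,
    clamp: bool = False,
    tol: float = 1e-6,
) -> tuple[CellState, CellState]:
    """Apply the division map to a cell at the division threshold.

    Parameters
    ----------
    state
        Cell state at the division instant; ``state.P`` must equal 1 within
        ``tol`` (the event tolerance of the integrator).
    div
        Size proportion ``s`` and retention coefficient ``re``.
    Q
        Damage resilience quotient.
    clamp
        If True, the retention coefficient is reduced to the analytic
        feasibility bound when the damage load makes the nominal ``re``
        infeasible; if False (default), infeasible retention raises
        :class:`InfeasibleRetentionError`.

    Returns
    -------
    (mother, daughter)
        Mother: ``(s - re (1-s) Q D, (s + (1-s) re) D)``.
        Daughter: ``((1-s) + re (1-s) Q D, (1-s)(1-re) D)``.
        Both share the event time ``state.tau``.
    """
    if abs(state.P - 1.0) > tol:
        raise InvalidStateError(
            f"divide() requires P = 1 at the division instant, got P={state.P}"
        )
    s, re, D = div.s, div.re, state.D
    if clamp:
        re = retention_clamp(s, re, Q, D)
    retained = re * (1.0 - s) * Q * D
    mother_P = s - retained
    if mother_P < 0:
        raise InfeasibleRetentionError(
            f"retention re={re} exceeds the feasibility bound "
            f"(2s-1)/((1-s) Q D) = {retention_clamp(s, 1.0, Q, D)} "
            f"at s={s}, Q={Q}, D={D}: mother P would be {mother_P}"
        )
    mother = CellState(P=mother_P, D=(s + (1.0 - s) * re) * D, tau=state.tau)
    daughter = CellState(
        P=(1.0 - s) + retained, D=(1.0 - s) * (1.0 - re) * D, tau=state.tau
    )
    return mother, daughter


def retention_clamp(s: float, re: float, Q: float, D: float) -> float:
    """Clamp a retention coefficient to the feasibility bound.

    Returns ``min(re, (2s-1)/((1-s) Q D))``, the largest retention that
    leaves the mother with at least the minimal viable protein content
    ``1 - s`` after division.  For D = 0 the bound is vacuous and ``re`` is
    returned unchanged.
    """
    if D <= 0:
        return re
    bound = (2.0 * s - 1.0) / ((1.0 - s) * Q * D)
    return min(re, bound)


def nondimensionalise(dim: DimensionalParameters) -> RateParameters:
    """Map dimensional parameters to the dimensionless rate parameters.

    Rates are scaled by the growth rate (``k1 <- k1/mu``, ``k2 <- k2/mu``)
    and the thresholds collapse into the resilience quotient
    ``Q = D_death / P_div``.  Under Monod growth mu is evaluated as
    ``mu_max S / (S + K_S)`` first.
    """
    mu = dim.growth_rate
    if mu == 0:
        raise ZeroDivisionError("growth rate mu is zero; cannot rescale rates")
    return RateParameters(
        g=dim.g, k1=dim.k1 / mu, k2=dim.k2 / mu, Q=dim.d_death / dim.p_div
    )


def observable(state: CellState, Q: float) -> float:
    """Dimensionless cell area y = P + Q D.

    A damage-free daughter at its division instant has y = 1; a cell at the
    death threshold has y = P + Q, so Q measures how much larger an old cell
    grows than a young one.
    """
    if not (math.isfinite(state.P) and math.isfinite(state.D)):
        raise InvalidStateError("state must be finite")
    return state.P + Q * state.D
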