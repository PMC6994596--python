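"""Closed-form constraints of the replicative-ageing model.

These are the analytic consequences of the division map and the continuous
dynamics: how much damage a mother can retain, how asymmetric a division can
be, when growth is possible at all, how much substrate that requires, and
where the steady states of the planar system sit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import InvalidStateError, RateParameters

__all__ = [
    "RetentionBound",
    "SteadyState",
    "retention_upper_bound",
    "max_asymmetry",
    "starvation_check",
    "minimal_substrate",
    "steady_states",
]

#: Zero tolerance for eigenvalue sign tests in stability labelling.
_EIG_TOL = 1e-12


@dataclass(frozen=True)
class RetentionBound:
    """Upper bound on the retention coefficient at a given damage load.

    ``re_max`` is the clamped (physical) bound in [0, 1]; ``raw`` the
    unclamped value (2s-1)/((1-s) Q D), which can exceed 1 for strongly
    asymmetric divisions.  ``vacuous`` marks the D = 0 case where any
    retention is feasible.
    """

    re_max: float
    raw: float
    s: float
    Q: float
    D: float
    clamped: bool
    vacuous: bool = False


def retention_upper_bound(s: float, Q: float, D: float) -> RetentionBound:
    """Maximal feasible retention coefficient at damage level D.

    Derived from requiring the mother to keep at least the minimal viable
    protein content 1 - s after division:

        re <= (1/Q) * ((2s - 1) / (1 - s)) * (1/D).

    The bound vanishes for symmetric division (s = 1/2): retention is a
    byproduct of asymmetry.  It decreases in D (aged cells retain less) and
    in Q (resilience trades off against retention).
    """
    if not 0.5 <= s < 1:
        raise InvalidStateError(f"s must lie in [0.5, 1), got {s}")
    if Q <= 0:
        raise InvalidStateError(f"Q must be positive, got {Q}")
    if D < 0 or D > 1:
        raise InvalidStateError(f"D must lie in [0, 1], got {D}")
    if D == 0:
        return RetentionBound(
            re_max=1.0, raw=math.inf, s=s, Q=Q, D=D, clamped=True, vacuous=True
        )
    raw = (2.0 * s - 1.0) / ((1.0 - s) * Q * D)
    return RetentionBound(
        re_max=min(1.0, raw), raw=raw, s=s, Q=Q, D=D, clamped=raw > 1.0
    )


def max_asymmetry(Q: float) -> float:
    """Maximal size proportion s_max = (Q + 1) / (Q + 2).

    The most asymmetric division at which full retention (re = 1) of a
    maximal damage load (D = 1) is still feasible.  Strictly increasing in
    Q and always below 1; for Q = 2.5 it evaluates to 0.777..., i.e. 0.8 at
    one-decimal precision, and exactly 0.8 at Q = 3.
    """
    if Q <= 0:
        raise InvalidStateError(f"Q must be positive, got {Q}")
    return (Q + 1.0) / (Q + 2.0)


def starvation_check(rate: RateParameters) -> bool:
    """True when growth is possible: k1 + k2 < g.

    Cells violating this bound spend more on damage turnover than growth
    provides and fall in the starvation region of parameter space.
    """
    return rate.k1 + rate.k2 < rate.g


def minimal_substrate(
    k1: float, k2: float, mu_max: float, g: float, K_S: float
) -> float:
    """Minimal substrate for growth under Monod kinetics.

    S_min = ((k1 + k2) / (mu_max g - (k1 + k2))) K_S; requires
    mu_max g > k1 + k2, otherwise no finite amount of substrate suffices.
    """
    total = k1 + k2
    if mu_max * g <= total:
        raise InvalidStateError(
            f"mu_max*g = {mu_max * g} must exceed k1 + k2 = {total}; "
            "no finite substrate amount sustains growth"
        )
    return total / (mu_max * g - total) * K_S


@dataclass(frozen=True)
class SteadyState:
    """A steady state of the planar dynamics with its stability label."""

    P: float
    D: float
    eigenvalues: tuple[complex, complex]
    stability: str  # stable | unstable | saddle | marginal


def _label(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.any(np.abs(re) <= _EIG_TOL):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def steady_states(rate: RateParameters) -> list[SteadyState]:
    """Steady states of the continuous dynamics with linear stability.

    The origin (0, 0) is always a steady state; its Jacobian determinant is
    -k2 g < 0, so it is a saddle for all valid parameters.  For k1 > 0 the
    interior steady state sits at (g Q k2 / k1, g); its damage coordinate
    D = g > 1 places it outside the viable unit box, which is what makes
    damage accumulation (and hence ageing) possible inside it.
    """
    g, k1, k2, Q = rate.g, rate.k1, rate.k2, rate.Q
    out: list[SteadyState] = []

    J0 = np.array([[g - k1, k2 * Q], [k1 / Q, -k2]])
    eig0 = np.linalg.eigvals(J0)
    out.append(
        SteadyState(
            P=0.0, D=0.0,
            eigenvalues=(complex(eig0[0]), complex(eig0[1])),
            stability=_label(eig0),
        )
    )
    if k1 > 0 and k2 > 0:
        P_star = g * Q * k2 / k1
        D_star = g
        # Jacobian of (P(g-D) - k1 P + k2 Q D, (k1/Q) P - k2 D) at the point
        J1 = np.array(
            [[g - D_star - k1, -P_star + k2 * Q], [k1 / Q, -k2]]
        )
        eig1 = np.linalg.eigvals(J1)
        out.append(
            SteadyState(
                P=P_star, D=D_star,
                eigenvalues=(complex(eig1[0]), complex(eig1[1])),
                stability=_label(eig1),
            )
        )
    return out
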