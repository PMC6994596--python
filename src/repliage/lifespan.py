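"""Single-lineage simulation: divisions, death, replicative lifespan, fate.

A lineage starts from one cell (typically a damage-free daughter at
``(P, D) = (1 - s, 0)``) and follows the *mother* through successive
divisions: at each P = 1 event the division map is applied and integration
continues with the mother state; a D = 1 event ends the lineage.  The
replicative lifespan (RLS) is the number of completed divisions.

Fates
-----
``starvation``
    k1 + k2 >= g: growth cannot outpace damage turnover (assigned
    analytically, without simulation).
``immortality``
    The post-division birth states converge to a fixed point of the
    division return map; the cell divides forever.
``ageing``
    At least one division, then death: finite positive RLS.
``clonal_senescence``
    Death before the first division (RLS = 0).
``censored``
    A simulation cap was reached before the fate could be decided.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _integrate
from .params import CellState, DivisionParameters, InfeasibleRetentionError, RateParameters

__all__ = [
    "Fate",
    "LifeHistory",
    "SimulationCaps",
    "simulate_lineage",
    "max_generation_time",
    "classify_fate",
    "history_to_frame",
]


class StagnationError(RuntimeError):
    """Neither threshold is reachable and the dynamics have stalled."""


class Fate(str, enum.Enum):
    STARVATION = "starvation"
    IMMORTALITY = "immortality"
    AGEING = "ageing"
    CLONAL_SENESCENCE = "clonal_senescence"
    CENSORED = "censored"


@dataclass(frozen=True)
class SimulationCaps:
    """Stopping rules and solver tolerances for lineage simulation.

    ``conv_tol`` is the max-norm tolerance under which successive
    post-division birth states are declared converged (immortality).
    """

    max_divisions: int = 1000
    max_tau: float = 1e4
    rtol: float = 1e-8
    atol: float = 1e-10
    conv_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_divisions < 1 or self.max_tau <= 0:
            raise ValueError("caps must be positive")


@dataclass(frozen=True)
class LifeHistory:
    """Event record of one simulated mother lineage."""

    division_times: np.ndarray
    division_damages: np.ndarray  # damage level at each division instant
    death_time: float | None
    death_P: float | None  # intact-protein level at the death instant
    fate: Fate
    init: CellState
    rate: RateParameters
    div: DivisionParameters

    @property
    def rls(self) -> int:
        """Replicative lifespan: the number of completed divisions."""
        return len(self.division_times)

    @property
    def generation_times(self) -> np.ndarray:
        """Inter-division intervals, the first measured from birth at tau=0."""
        if self.rls == 0:
            return np.empty(0)
        return np.diff(np.concatenate(([self.init.tau], self.division_times)))

    @property
    def terminal_interval(self) -> float | None:
        """Interval from the last division to death, if the cell died."""
        if self.death_time is None or self.rls == 0:
            return None
        return self.death_time - self.division_times[-1]


def simulate_lineage(
    rate: RateParameters,
    div: DivisionParameters,
    init: CellState | None = None,
    caps: SimulationCaps = SimulationCaps(),
) -> LifeHistory:
    """Integrate the lineage of a single mother cell until death or a cap.

    The continuous dynamics are integrated with an adaptive RKF4(5) method;
    the P = 1 and D = 1 events are located by bisection.  When both events
    fall inside one step the earlier one wins and exact ties resolve to
    death.  ``init`` defaults to a damage-free daughter ``(1 - s, 0)``.
    """
    if init is None:
        init = CellState(P=1.0 - div.s, D=0.0)
    if init.P >= 1.0 or init.D >= 1.0:
        raise ValueError("initial state must lie strictly inside the unit box")
    div_times, div_damages, n, death_time, death_P, status = _integrate._run_lineage(
        rate.g, rate.k1, rate.k2, rate.Q, div.s, div.re,
        init.P, init.D, caps.max_divisions, caps.max_tau,
        caps.rtol, caps.atol, caps.conv_tol,
    )
    if status == -1:
        raise InfeasibleRetentionError(
            f"retention re={div.re} became infeasible during the lineage "
            f"(mother P < 0); the bound is (2s-1)/((1-s) Q D)"
        )
    if status == _integrate.STATUS_DEATH:
        fate = Fate.AGEING if n > 0 else Fate.CLONAL_SENESCENCE
        death: float | None = float(death_time)
    elif status == _integrate.STATUS_IMMORTAL:
        fate = Fate.IMMORTALITY
        death = None
    else:
        # caps reached without death or convergence
        if status == _integrate.STATUS_TAU_CAP and n == 0:
            dP, dD = _derivative_norm(rate, init)
            if max(dP, dD) < 1e-12:
                raise StagnationError(
                    "dynamics stalled inside the unit box; no threshold reachable"
                )
        fate = Fate.CENSORED
        death = None
    return LifeHistory(
        division_times=np.asarray(div_times, dtype=float),
        division_damages=np.asarray(div_damages, dtype=float),
        death_time=death,
        death_P=float(death_P) if status == _integrate.STATUS_DEATH else None,
        fate=fate,
        init=init,
        rate=rate,
        div=div,
    )


def _derivative_norm(rate: RateParameters, state: CellState) -> tuple[float, float]:
    from .core import derivatives

    dP, dD = derivatives(state, rate)
    return abs(dP), abs(dD)


def max_generation_time(
    history: LifeHistory, include_terminal: bool = True
) -> float:
    """Longest generation time of a lineage, in dimensionless time.

    Generation times are the inter-division intervals, the first measured
    from birth.  With ``include_terminal`` (the default) the interval from
    the last division to death also counts when the cell died; for the
    lineages studied here that final, never-completed generation is the
    longest, because growth slows as damage approaches the death threshold.
    """
    if history.rls == 0:
        raise ValueError("history has no divisions; generation times undefined")
    gmax = float(np.max(history.generation_times))
    term = history.terminal_interval
    if include_terminal and term is not None:
        gmax = max(gmax, term)
    return gmax


def classify_fate(
    rate: RateParameters,
    div: DivisionParameters,
    caps: SimulationCaps = SimulationCaps(),
) -> Fate:
    """Classify the fate of a damage-free daughter under given parameters.

    Starvation (k1 + k2 >= g) is decided analytically; k1 = 0 (no damage
    formation from a damage-free start) is immortal by construction; all
    other parameters are classified by simulation.  Cap-limited runs are
    labelled censored, never silently assigned a fate.
    """
    if rate.k1 + rate.k2 >= rate.g:
        return Fate.STARVATION
    if rate.k1 == 0:
        return Fate.IMMORTALITY
    return simulate_lineage(rate, div, caps=caps).fate


def history_to_frame(history: LifeHistory, lineage_id: str = "0") -> pd.DataFrame:
    """Flatten a life history to one event per row.

    Columns: lineage id, event type (division/death), tau, P, D; P and D are
    the values at the event instant (P = 1 at divisions, D = 1 at death).
    """
    rows = []
    for t, d in zip(history.division_times, history.division_damages):
        rows.append((lineage_id, "division", float(t), 1.0, float(d)))
    if history.death_time is not None:
        death_P = history.death_P if history.death_P is not None else math.nan
        rows.append((lineage_id, "death", float(history.death_time), death_P, 1.0))
    return pd.DataFrame(
        rows, columns=["lineage_id", "event", "tau", "P", "D"]
    )
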