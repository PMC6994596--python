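"""Cell-area time series: synthetic generation, least squares and AIC.

The link between the model and microscopy data is the observable
y = P + Q D, the total protein content in division-threshold units, taken to
be proportional to the measured cell area.  The synthetic generator emulates
the experimental design of time-lapse cohorts: a few damage-free daughters
("young") and several high-damage mothers ("old"), each sampled on a common
time grid with additive Gaussian measurement noise.

Because several parameters of the model are structurally unidentifiable from
area data alone, the resilience quotient Q and the area scale are fixed
during fitting by default; the estimated vector is theta = (g, k1, k2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import _integrate
from .lifespan import SimulationCaps, simulate_lineage
from .params import CellState, DivisionParameters, RateParameters

__all__ = [
    "AreaTrajectory",
    "FitResult",
    "generate_synthetic_trajectories",
    "least_squares_objective",
    "aic",
    "fit",
    "write_trajectories",
    "read_trajectories",
]

#: Penalty residual magnitude when the model dies inside the observation
#: window; large but finite so optimisers can traverse the region.
_DEATH_PENALTY = 1e3


@dataclass(frozen=True)
class AreaTrajectory:
    """One cell's area-vs-time series.

    ``initial_state`` records the (P, D) the series started from; the
    synthetic generator always fills it, and the fitting layer uses it as
    the known initial condition of the ODE prediction.  ``truncated`` marks
    series cut short by a division or death event.
    """

    cell_id: str
    times: np.ndarray
    areas: np.ndarray
    cohort: str  # "young" | "old"
    initial_state: CellState | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and areas must be matching 1-D arrays")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("areas must be positive")
        if self.cohort not in ("young", "old"):
            raise ValueError(f"cohort must be 'young' or 'old', got {self.cohort}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "areas", a)

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multistart least-squares fit."""

    theta_hat: RateParameters
    ls: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    seed: int | None
    n_starts: int
    scale: float = 1.0


def _old_cell_state(
    rate: RateParameters, div: DivisionParameters, age: int,
    caps: SimulationCaps,
) -> CellState:
    """Birth state of a mother ``age`` divisions before its death.

    Simulates the full lineage of a damage-free daughter and returns the
    post-division state ``age`` divisions from the end, giving the
    elevated-damage starting points of the "old" cohort.
    """
    history = simulate_lineage(rate, div, caps=caps)
    if history.rls < 1:
        raise ValueError("parameters do not produce a dividing lineage")
    idx = max(history.rls - 1 - age, 0)
    D_at = history.division_damages[idx]
    s, re, Q = div.s, div.re, rate.Q
    return CellState(
        P=s - re * (1.0 - s) * Q * D_at,
        D=(s + (1.0 - s) * re) * D_at,
    )


def generate_synthetic_trajectories(
    rate: RateParameters,
    div: DivisionParameters,
    n_young: int = 3,
    n_old: int = 5,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    relative_noise: bool = False,
    scale: float = 1.0,
    seed: int | None = None,
    caps: SimulationCaps = SimulationCaps(),
) -> list[AreaTrajectory]:
    """Simulate area series for cohorts of young and old cells.

    Young cells start from the damage-free daughter state (1 - s, 0); old
    cells from mother states one to ``n_old`` divisions before death in a
    simulated lineage, so their damage loads are staggered.  Areas are
    ``scale * (P + Q D)`` plus i.i.d. Gaussian noise of standard deviation
    ``noise_sd`` (absolute units, or a fraction of the signal when
    ``relative_noise``).  Series reaching a division or death event are
    truncated there and flagged.  Reproducible given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if times is None:
        # one full generation of a damage-free daughter (first division near
        # tau = 1.9), mirroring imaging through at least one division; cells
        # reaching an event earlier are truncated there
        times = np.linspace(0.0, 2.0, 41)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    trajectories: list[AreaTrajectory] = []

    young_init = CellState(P=1.0 - div.s, D=0.0)
    inits = [("young", f"young_{i}", young_init) for i in range(n_young)]
    for i in range(n_old):
        state = _old_cell_state(rate, div, age=i, caps=caps)
        inits.append(("old", f"old_{i}", state))

    for cohort, cell_id, init in inits:
        Ps, Ds, n_valid, code = _integrate._observe_on_grid(
            init.P, init.D, times, rate.g, rate.k1, rate.k2, rate.Q,
            caps.rtol, caps.atol,
        )
        y = scale * (Ps[:n_valid] + rate.Q * Ds[:n_valid])
        if noise_sd > 0:
            sd = noise_sd * y if relative_noise else noise_sd
            y = y + rng.normal(0.0, 1.0, size=len(y)) * sd
        y = np.maximum(y, 1e-12)  # areas are positive by construction
        trajectories.append(
            AreaTrajectory(
                cell_id=cell_id,
                times=times[:n_valid],
                areas=y,
                cohort=cohort,
                initial_state=init,
                truncated=code != _integrate.NO_EVENT,
            )
        )
    return trajectories


def _predict(
    theta: np.ndarray, traj: AreaTrajectory, Q: float, scale: float,
    rtol: float, atol: float,
) -> np.ndarray:
    g, k1, k2 = theta
    init = traj.initial_state
    if init is None:
        raise ValueError(
            f"trajectory {traj.cell_id} carries no initial state; "
            "the ODE prediction needs one"
        )
    Ps, Ds, n_valid, _code = _integrate._observe_on_grid(
        init.P, init.D, traj.times, g, k1, k2, Q, rtol, atol
    )
    y = scale * (Ps + Q * Ds)
    if n_valid < len(traj.times):
        # death/division inside the window: penalise the missing tail
        y[n_valid:] = traj.areas[n_valid:] + _DEATH_PENALTY
    return y


def least_squares_objective(
    theta: np.ndarray | tuple[float, float, float],
    trajectories: list[AreaTrajectory],
    Q: float,
    scale: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Sum of squared area residuals over all trajectories and time points.

    ``theta = (g, k1, k2)``; Q and the area scale are held fixed.  Parameter
    sets under which the model cell dies before the observation window ends
    incur a large finite penalty on the unreachable points rather than an
    exception, so optimisers can move through them.
    """
    res = _residuals(np.asarray(theta, dtype=float), trajectories, Q, scale,
                     rtol, atol)
    return float(np.sum(res**2))


def _residuals(theta, trajectories, Q, scale, rtol, atol) -> np.ndarray:
    out = []
    for traj in trajectories:
        pred = _predict(theta, traj, Q, scale, rtol, atol)
        out.append(pred - traj.areas)
    return np.concatenate(out)


def aic(ls: float, n_obs: int, n_params: int) -> float:
    """Akaike information criterion under Gaussian residuals.

    AIC = n ln(LS / n) + 2 p, dropping additive constants; lower is better.
    LS must be positive (an exact-zero fit has no finite Gaussian
    likelihood scale; jitter the data or report the fit as exact).
    """
    if ls <= 0:
        raise ValueError("ls must be positive; an exact fit has no AIC scale")
    if n_obs <= n_params:
        raise ValueError("need more observations than parameters")
    return n_obs * math.log(ls / n_obs) + 2 * n_params


def fit(
    trajectories: list[AreaTrajectory],
    Q: float,
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (1.0 + 1e-6, 0.0, 0.0),
        (2.0, 1.0, 1.0),
    ),
    n_starts: int = 8,
    seed: int | None = None,
    scale: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Multistart bounded least-squares estimation of theta = (g, k1, k2).

    Starts are drawn uniformly inside the bounds from a seeded generator;
    each is refined with a trust-region-reflective least-squares solve and
    the best converged minimum wins.  Q and the area scale stay fixed.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    rng = np.random.default_rng(seed)
    n_obs = sum(t.n_obs for t in trajectories)

    best = None
    any_converged = False
    for _ in range(n_starts):
        x0 = lo + rng.uniform(size=3) * (hi - lo)
        sol = least_squares(
            _residuals, x0, bounds=(lo, hi),
            args=(trajectories, Q, scale, rtol, atol),
            xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        ls = float(np.sum(sol.fun**2))
        if best is None or ls < best[0]:
            best = (ls, sol.x, bool(sol.success))
        any_converged = any_converged or sol.success

    ls, x, success = best
    theta_hat = RateParameters(g=float(x[0]), k1=float(x[1]), k2=float(x[2]), Q=Q)
    aic_value = (
        aic(ls, n_obs, 3) if ls > 0 and n_obs > 3 else -math.inf
    )
    return FitResult(
        theta_hat=theta_hat, ls=ls, aic=aic_value, n_obs=n_obs, n_params=3,
        converged=success and any_converged, seed=seed, n_starts=n_starts,
        scale=scale,
    )


def write_trajectories(
    trajectories: list[AreaTrajectory], path: str | Path
) -> None:
    """Write trajectories as delimited text, one observation per row.

    Columns: cell_id, time, area, cohort, and (when known) the initial
    state P0, D0 used to generate the series.
    """
    rows = []
    for t in trajectories:
        P0 = t.initial_state.P if t.initial_state else math.nan
        D0 = t.initial_state.D if t.initial_state else math.nan
        for ti, ai in zip(t.times, t.areas):
            rows.append((t.cell_id, ti, ai, t.cohort, P0, D0))
    pd.DataFrame(
        rows, columns=["cell_id", "time", "area", "cohort", "P0", "D0"]
    ).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[AreaTrajectory]:
    """Read trajectories written by :func:`write_trajectories`."""
    frame = pd.read_csv(path)
    out = []
    for cell_id, group in frame.groupby("cell_id", sort=False):
        P0 = group["P0"].iloc[0]
        D0 = group["D0"].iloc[0]
        init = (
            CellState(P=float(P0), D=float(D0))
            if not (math.isnan(P0) or math.isnan(D0))
            else None
        )
        out.append(
            AreaTrajectory(
                cell_id=str(cell_id),
                times=group["time"].to_numpy(),
                areas=group["area"].to_numpy(),
                cohort=str(group["cohort"].iloc[0]),
                initial_state=init,
            )
        )
    return out
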