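"""Low-level event-driven integrator for the planar damage-accumulation ODE.

Implements an adaptive Runge-Kutta-Fehlberg 4(5) stepper with threshold-event
localisation, compiled with numba.  Events (P = 1 division, D = 1 death) are
located by bisection on the step size: each trial is a genuine error-controlled
RKF45 step from the last accepted state, so the event time inherits the
integration accuracy rather than an interpolant's.  If both thresholds are
crossed within one accepted step the earlier crossing wins; exact ties resolve
to death.

The module is internal; user-facing entry points live in
:mod:`repliage.lifespan` and :mod:`repliage.fitting`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Event codes returned by _advance_to_event.
NO_EVENT = 0
DIVISION = 1
DEATH = 2

_SAFETY = 0.9
_MIN_FACTOR = 0.1
_MAX_FACTOR = 5.0


@njit(cache=True, inline="always")
def _rhs(P, D, g, k1, k2, Q):
    dP = P * (g - D) - k1 * P + k2 * Q * D
    dD = (k1 / Q) * P - k2 * D
    return dP, dD


@njit(cache=True)
def _rkf45_step(P, D, h, g, k1, k2, Q):
    """One Runge-Kutta-Fehlberg 4(5) step of size h.

    Returns (P5, D5, err) where (P5, D5) is the 5th-order solution and err
    the max-norm of the embedded 4th/5th-order difference.
    """
    k1P, k1D = _rhs(P, D, g, k1, k2, Q)

    k2P, k2D = _rhs(P + h * 0.25 * k1P, D + h * 0.25 * k1D, g, k1, k2, Q)

    k3P, k3D = _rhs(
        P + h * (3.0 / 32.0 * k1P + 9.0 / 32.0 * k2P),
        D + h * (3.0 / 32.0 * k1D + 9.0 / 32.0 * k2D),
        g, k1, k2, Q,
    )
    k4P, k4D = _rhs(
        P + h * (1932.0 / 2197.0 * k1P - 7200.0 / 2197.0 * k2P + 7296.0 / 2197.0 * k3P),
        D + h * (1932.0 / 2197.0 * k1D - 7200.0 / 2197.0 * k2D + 7296.0 / 2197.0 * k3D),
        g, k1, k2, Q,
    )
    k5P, k5D = _rhs(
        P + h * (439.0 / 216.0 * k1P - 8.0 * k2P + 3680.0 / 513.0 * k3P - 845.0 / 4104.0 * k4P),
        D + h * (439.0 / 216.0 * k1D - 8.0 * k2D + 3680.0 / 513.0 * k3D - 845.0 / 4104.0 * k4D),
        g, k1, k2, Q,
    )
    k6P, k6D = _rhs(
        P + h * (-8.0 / 27.0 * k1P + 2.0 * k2P - 3544.0 / 2565.0 * k3P
                 + 1859.0 / 4104.0 * k4P - 11.0 / 40.0 * k5P),
        D + h * (-8.0 / 27.0 * k1D + 2.0 * k2D - 3544.0 / 2565.0 * k3D
                 + 1859.0 / 4104.0 * k4D - 11.0 / 40.0 * k5D),
        g, k1, k2, Q,
    )

    P5 = P + h * (16.0 / 135.0 * k1P + 6656.0 / 12825.0 * k3P
                  + 28561.0 / 56430.0 * k4P - 9.0 / 50.0 * k5P + 2.0 / 55.0 * k6P)
    D5 = D + h * (16.0 / 135.0 * k1D + 6656.0 / 12825.0 * k3D
                  + 28561.0 / 56430.0 * k4D - 9.0 / 50.0 * k5D + 2.0 / 55.0 * k6D)
    P4 = P + h * (25.0 / 216.0 * k1P + 1408.0 / 2565.0 * k3P
                  + 2197.0 / 4104.0 * k4P - 1.0 / 5.0 * k5P)
    D4 = D + h * (25.0 / 216.0 * k1D + 1408.0 / 2565.0 * k3D
                  + 2197.0 / 4104.0 * k4D - 1.0 / 5.0 * k5D)

    err = max(abs(P5 - P4), abs(D5 - D4))
    return P5, D5, err


@njit(cache=True)
def _locate_crossing(P, D, h_hi, g, k1, k2, Q, component):
    """Bisect the step size to land on the threshold crossing of a component.

    Assumes the component is below 1 at h=0 and at/above 1 at h=h_hi.  Each
    trial evaluates one RKF45 step of the candidate size from the accepted
    state, so the located time is as accurate as the integration itself.
    Returns (h_star, P_star, D_star).
    """
    lo = 0.0
    hi = h_hi
    Ph, Dh = P, D
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        Pm, Dm, _err = _rkf45_step(P, D, mid, g, k1, k2, Q)
        val = Pm if component == 0 else Dm
        if val >= 1.0:
            hi = mid
            Ph, Dh = Pm, Dm
        else:
            lo = mid
        if hi - lo <= 1e-15 * max(1.0, hi):
            break
    return hi, Ph, Dh


@njit(cache=True)
def _advance_to_event(P, D, t0, t_max, g, k1, k2, Q, rtol, atol):
    """Integrate from (P, D) at t0 until P or D crosses 1, or t_max.

    Returns (code, t, P, D) with code NO_EVENT, DIVISION or DEATH.  The
    crossing component is clipped to exactly 1 in the returned state.
    """
    t = t0
    h = 0.01
    while t < t_max:
        if h > t_max - t:
            h = t_max - t
        if h < 1e-14 * max(1.0, abs(t)):
            break
        Pn, Dn, err = _rkf45_step(P, D, h, g, k1, k2, Q)
        scale = atol + rtol * max(max(abs(P), abs(Pn)), max(abs(D), abs(Dn)))
        if err > scale:
            factor = _SAFETY * (scale / err) ** 0.2
            if factor < _MIN_FACTOR:
                factor = _MIN_FACTOR
            h *= factor
            continue
        # accepted step; check upward threshold crossings
        crossed_P = P < 1.0 <= Pn
        crossed_D = D < 1.0 <= Dn
        if crossed_P or crossed_D:
            hP = np.inf
            hD = np.inf
            PP = P
            PD = D
            DP = P
            DD = D
            if crossed_P:
                hP, PP, PD = _locate_crossing(P, D, h, g, k1, k2, Q, 0)
            if crossed_D:
                hD, DP, DD = _locate_crossing(P, D, h, g, k1, k2, Q, 1)
            if hD <= hP:  # ties resolve to death
                return DEATH, t + hD, DP, 1.0
            return DIVISION, t + hP, 1.0, PD
        t += h
        P, D = Pn, Dn
        if err > 0.0:
            factor = _SAFETY * (scale / err) ** 0.2
            if factor > _MAX_FACTOR:
                factor = _MAX_FACTOR
            h *= factor
        else:
            h *= _MAX_FACTOR
    return NO_EVENT, t, P, D


# Lineage status codes.
STATUS_DEATH = 0
STATUS_IMMORTAL = 1
STATUS_DIV_CAP = 2
STATUS_TAU_CAP = 3


@njit(cache=True)
def _run_lineage(g, k1, k2, Q, s, re, P0, D0, max_divisions, max_tau,
                 rtol, atol, conv_tol):
    """Follow the mother lineage through divisions until death or a cap.

    Returns (div_times, div_damages, n_div, death_time, death_P, status)
    where div_times[i] is the time of the i-th division and div_damages[i]
    the damage level at that instant (pre-division).  death_time and death_P
    are NaN unless status == STATUS_DEATH.
    """
    div_times = np.empty(max_divisions)
    div_damages = np.empty(max_divisions)
    n = 0
    t = 0.0
    P, D = P0, D0
    prev_P = np.nan
    prev_D = np.nan
    status = STATUS_DIV_CAP
    death_time = np.nan
    death_P = np.nan
    while n < max_divisions:
        code, te, Pe, De = _advance_to_event(P, D, t, max_tau, g, k1, k2, Q,
                                             rtol, atol)
        if code == NO_EVENT:
            status = STATUS_TAU_CAP
            break
        if code == DEATH:
            status = STATUS_DEATH
            death_time = te
            death_P = Pe
            break
        # division: record and apply the mother map
        div_times[n] = te
        div_damages[n] = De
        n += 1
        t = te
        P = s - re * (1.0 - s) * Q * De
        D = (s + (1.0 - s) * re) * De
        if P < 0.0:
            # infeasible retention; surfaced by the caller
            status = -1
            break
        if n > 1 and abs(P - prev_P) < conv_tol and abs(D - prev_D) < conv_tol:
            status = STATUS_IMMORTAL
            break
        prev_P, prev_D = P, D
    return div_times[:n], div_damages[:n], n, death_time, death_P, status


@njit(cache=True)
def _observe_on_grid(P0, D0, ts, g, k1, k2, Q, rtol, atol):
    """Integrate from (P0, D0) and record (P, D) at the sample times ts.

    Integration stops at the first threshold event; samples past the event
    are NaN.  Returns (P_arr, D_arr, n_valid, code) where code is the event
    that truncated the trajectory (NO_EVENT if none).
    """
    m = ts.shape[0]
    Ps = np.full(m, np.nan)
    Ds = np.full(m, np.nan)
    P, D = P0, D0
    t = ts[0]
    Ps[0] = P
    Ds[0] = D
    for i in range(1, m):
        code, te, Pe, De = _advance_to_event(P, D, t, ts[i], g, k1, k2, Q,
                                             rtol, atol)
        if code != NO_EVENT:
            return Ps, Ds, i, code
        t = te
        P, D = Pe, De
        Ps[i] = P
        Ds[i] = D
    return Ps, Ds, m, NO_EVENT
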