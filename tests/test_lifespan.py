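"""Lineage simulation: events, lifespan, generation times, fate labels.

The frozen lifespan and event-time values for the reference parameter set
(g=1.1, k1=0.5, k2=0.1, s=0.6370, re=0.2902, damage-free daughter start)
were confirmed by two independent integrations: scipy's solve_ivp (RK45 with
terminal events, rtol 1e-10) and R deSolve's lsodar root-finding, which agree
with the package to six decimals.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from repliage import (
    CellState,
    DivisionParameters,
    Fate,
    RateParameters,
    SimulationCaps,
    classify_fate,
    divide,
    max_generation_time,
    simulate_lineage,
)
from repliage.lifespan import history_to_frame

# (Q, rls, death_time, terminal interval), oracle-confirmed at converged
# tolerances for the reference parameter set.
REFERENCE_LINEAGES = [
    (2.6, 5, 15.001025, 5.9980),
    (2.8, 8, 23.348054, 6.6454),
    (3.0, 14, 40.400351, 7.0426),
]


class TestReferenceLineages:
    @pytest.mark.parametrize("Q, rls, death, terminal", REFERENCE_LINEAGES)
    def test_lifespan_and_event_times(
        self, Q, rls, death, terminal, reference_division
    ):
        rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=Q)
        history = simulate_lineage(rate, reference_division)
        assert history.fate == Fate.AGEING
        assert history.rls == rls
        assert history.death_time == pytest.approx(death, abs=1e-4)
        assert history.terminal_interval == pytest.approx(terminal, abs=1e-4)

    def test_rls_nondecreasing_in_resilience(self, reference_division):
        """Raising Q at fixed rates never shortens the lifespan."""
        rls = []
        for Q in (2.2, 2.4, 2.6, 2.8, 3.0):
            rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=Q)
            rls.append(simulate_lineage(rate, reference_division).rls)
        assert all(a <= b for a, b in zip(rls, rls[1:]))

    def test_agrees_with_scipy_event_integration(self, reference_division):
        """Division times match an independent solve_ivp event integration."""
        rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=2.6)
        s, re, Q = reference_division.s, reference_division.re, rate.Q

        def rhs(t, y):
            P, D = y
            return [
                P * (rate.g - D) - rate.k1 * P + rate.k2 * Q * D,
                (rate.k1 / Q) * P - rate.k2 * D,
            ]

        div_ev = lambda t, y: y[0] - 1.0
        death_ev = lambda t, y: y[1] - 1.0
        div_ev.terminal = death_ev.terminal = True
        tau, P, D = 0.0, 1 - s, 0.0
        div_times = []
        for _ in range(50):
            sol = solve_ivp(
                rhs, (tau, tau + 1e3), [P, D], events=[div_ev, death_ev],
                rtol=1e-10, atol=1e-12,
            )
            if len(sol.t_events[1]):
                death = sol.t_events[1][0]
                break
            tau = sol.t_events[0][0]
            div_times.append(tau)
            D_at = sol.y_events[0][0][1]
            P = s - re * (1 - s) * Q * D_at
            D = (s + (1 - s) * re) * D_at

        history = simulate_lineage(rate, reference_division)
        np.testing.assert_allclose(history.division_times, div_times, atol=1e-6)
        assert history.death_time == pytest.approx(death, abs=1e-6)

    def test_tolerance_refinement_is_stable(self, reference_division):
        """10x tighter tolerances move event times below reporting precision."""
        rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=2.8)
        coarse = simulate_lineage(
            rate, reference_division, caps=SimulationCaps(rtol=1e-8, atol=1e-10)
        )
        fine = simulate_lineage(
            rate, reference_division, caps=SimulationCaps(rtol=1e-9, atol=1e-11)
        )
        assert coarse.rls == fine.rls
        np.testing.assert_allclose(
            coarse.division_times, fine.division_times, atol=1e-5
        )
        assert coarse.death_time == pytest.approx(fine.death_time, abs=1e-5)


def _make_history(div_times, death_time, div):
    """Fabricate a LifeHistory with given event times for arithmetic tests."""
    from repliage import LifeHistory

    times = np.asarray(div_times, dtype=float)
    return LifeHistory(
        division_times=times,
        division_damages=np.full_like(times, 0.5),
        death_time=death_time,
        death_P=0.5 if death_time is not None else None,
        fate=Fate.AGEING if len(times) else Fate.CLONAL_SENESCENCE,
        init=CellState(P=1 - div.s, D=0.0),
        rate=RateParameters(g=1.1, k1=0.5, k2=0.1, Q=2.6),
        div=div,
    )


class TestGenerationTimes:
    def test_max_generation_time_reference_values(self, reference_division):
        """The longest generation is the terminal one; frozen oracle values."""
        for Q, _, _, terminal in REFERENCE_LINEAGES:
            rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=Q)
            history = simulate_lineage(rate, reference_division)
            assert max_generation_time(history) == pytest.approx(
                terminal, abs=1e-4
            )
            # completed generations only: strictly shorter than the terminal
            assert max_generation_time(history, include_terminal=False) < terminal

    def test_interval_arithmetic(self, reference_division):
        """Division times [1, 3, 6] give generation times 1, 2, 3."""
        history = _make_history([1.0, 3.0, 6.0], None, reference_division)
        np.testing.assert_allclose(history.generation_times, [1, 2, 3])
        assert max_generation_time(history) == 3

    def test_specific_generations_shorten_with_resilience(
        self, reference_division
    ):
        """Early generation times are shorter for more resilient cells."""
        gens = {}
        for Q in (2.6, 3.0):
            rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=Q)
            gens[Q] = simulate_lineage(rate, reference_division).generation_times
        assert gens[3.0][2] < gens[2.6][2]

    def test_requires_a_division(self, reference_division):
        history = _make_history([], 2.0, reference_division)
        with pytest.raises(ValueError):
            max_generation_time(history)


class TestFates:
    def test_starvation_decided_analytically(self, caps):
        rate = RateParameters(g=1.1, k1=0.6, k2=0.6, Q=2.6)
        assert classify_fate(rate, DivisionParameters(s=0.64), caps) == Fate.STARVATION

    def test_no_damage_formation_is_immortal(self, caps):
        rate = RateParameters(g=1.1, k1=0.0, k2=0.1, Q=2.6)
        div = DivisionParameters(s=0.64)
        assert classify_fate(rate, div, caps) == Fate.IMMORTALITY
        # and by simulation from (0.5, 0): D stays 0, birth states converge
        history = simulate_lineage(rate, div, init=CellState(P=0.5, D=0.0))
        assert history.fate == Fate.IMMORTALITY
        assert history.death_time is None

    def test_reference_parameters_age(self, caps, reference_division):
        rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=2.8)
        assert classify_fate(rate, reference_division, caps) == Fate.AGEING

    def test_clonal_senescence_dies_without_dividing(self, caps):
        # heavy damage formation, no repair: death before the first division
        rate = RateParameters(g=1.1, k1=1.05, k2=0.0, Q=0.8)
        div = DivisionParameters(s=0.64)
        history = simulate_lineage(rate, div, caps=caps)
        assert history.fate == Fate.CLONAL_SENESCENCE
        assert history.rls == 0
        assert classify_fate(rate, div, caps) == Fate.CLONAL_SENESCENCE

    def test_monotone_in_damage_formation_and_repair(self, caps):
        """RLS falls with k1 (fixed k2=0.06) and rises with k2 (fixed k1=0.46)."""
        div = DivisionParameters(s=0.64, re=0.299)

        def rls_or_inf(k1, k2):
            rate = RateParameters(g=1.1, k1=k1, k2=k2, Q=2.6)
            history = simulate_lineage(rate, div, caps=caps)
            if history.fate in (Fate.AGEING, Fate.CLONAL_SENESCENCE):
                return history.rls
            return float("inf")  # immortal (or cap-censored near the boundary)

        along_k1 = [rls_or_inf(k1, 0.06) for k1 in (0.32, 0.42, 0.46, 0.50, 0.65)]
        assert all(a >= b for a, b in zip(along_k1, along_k1[1:]))
        along_k2 = [rls_or_inf(0.46, k2) for k2 in (0.02, 0.06, 0.1, 0.2)]
        assert all(a <= b for a, b in zip(along_k2, along_k2[1:]))


class TestTrajectoryInvariants:
    def test_states_monotone_and_boxed_between_events(self, reference_division):
        """P and D grow monotonically and stay in the unit box pre-division."""
        from repliage import _integrate

        rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=2.6)
        ts = np.linspace(0.0, 1.8, 200)
        Ps, Ds, n_valid, code = _integrate._observe_on_grid(
            1 - reference_division.s, 0.0, ts,
            rate.g, rate.k1, rate.k2, rate.Q, 1e-8, 1e-10,
        )
        Ps, Ds = Ps[:n_valid], Ds[:n_valid]
        assert np.all(np.diff(Ps) > 0) and np.all(np.diff(Ds) > 0)
        assert np.all((Ps <= 1) & (Ps >= 0) & (Ds <= 1) & (Ds >= 0))


class TestSerialisation:
    def test_event_table_round_trip_structure(self, reference_division):
        rate = RateParameters(g=1.1, k1=0.5, k2=0.1, Q=2.6)
        history = simulate_lineage(rate, reference_division)
        frame = history_to_frame(history, lineage_id="L1")
        assert list(frame.columns) == ["lineage_id", "event", "tau", "P", "D"]
        assert (frame["event"] == "division").sum() == history.rls
        assert (frame["event"] == "death").sum() == 1
        assert frame["tau"].is_monotonic_increasing
        # division rows sit exactly at the division threshold
        assert (frame.loc[frame["event"] == "division", "P"] == 1.0).all()
        assert frame.loc[frame["event"] == "death", "D"].iloc[0] == 1.0
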