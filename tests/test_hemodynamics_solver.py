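"""1D network solver: rest state, wave physics, conservation, boundaries."""

import math

import numpy as np
import pytest

from lvsa.hemodynamics_solver import (
    SASolver,
    SolverError,
    SolverSettings,
    interior_step,
    run_sa,
    terminal_impedances,
)
from lvsa.io_fixtures import make_inflow, make_test_network
from lvsa.network_model import (
    ArterialNetwork,
    TubeLawParams,
    VesselSegment,
    wave_speed,
)
from lvsa.structured_tree import ImpedanceSpectrum, TreeParams
from lvsa.units import MMHG


def _resistive_spectrum(R: float, t_period: float, N: int) -> ImpedanceSpectrum:
    """Purely resistive terminal: z(t) = R delta(t) (single spike)."""
    z = np.zeros(N)
    dt = t_period / N
    z[0] = R / dt
    omega = 2 * math.pi * np.arange(N // 2 + 1) / t_period
    return ImpedanceSpectrum(t_period=t_period, N=N, omega=omega,
                             Z=np.full(N // 2 + 1, complex(R)), z=z)


def _single_vessel(law=None, length=12.0, r=0.4):
    seg = VesselSegment(id=1, name="v", length=length, r_top=r, r_bottom=r,
                        bed_root_radius=r)
    return ArterialNetwork([seg], 1, law or TubeLawParams())


SETT = SolverSettings(dt=0.9 / 2048, t_period=0.9)


class TestRestState:
    def test_uniform_vessel_exact_rest(self):
        net = _single_vessel()
        beds = {1: _resistive_spectrum(100.0, SETT.t_period, SETT.steps_per_period)}
        solver = SASolver(net, SETT, beds)
        A0 = solver.state.A[1].copy()
        for _ in range(200):
            solver.step(0.0)
        assert np.array_equal(solver.state.Q[1], np.zeros_like(A0))
        assert np.array_equal(solver.state.A[1], A0)

    def test_tapered_network_exact_rest(self):
        # taper + junctions + structured-tree terminals, nonzero P0
        law = TubeLawParams(P0=50 * MMHG)
        net = make_test_network("symmetric_bifurcation", law)
        beds = terminal_impedances(net, TreeParams(), SETT)
        solver = SASolver(net, SETT, beds)
        snapshot = solver.state.copy()
        for _ in range(200):
            solver.step(0.0)
        for sid in net.segments:
            assert np.max(np.abs(solver.state.Q[sid])) == 0.0
            assert np.array_equal(solver.state.A[sid], snapshot.A[sid])

    def test_interior_step_leaves_boundaries(self):
        net = _single_vessel()
        from lvsa.hemodynamics_solver import NetworkDiscretization

        disc = NetworkDiscretization(net, SETT)
        st = disc.rest_state()
        st.Q[1][3:6] = 1.0  # interior disturbance
        new = interior_step(st, disc)
        assert new.Q[1][0] == st.Q[1][0]
        assert new.Q[1][-1] == st.Q[1][-1]
        assert new.t == pytest.approx(st.t + SETT.dt)


class TestWavePhysics:
    def test_small_pulse_travels_at_tube_law_speed(self):
        # effectively frictionless long uniform vessel
        law = TubeLawParams(nu=1e-9, delta_star=1.0)
        net = _single_vessel(law, length=100.0, r=0.5)
        sett = SolverSettings(dt=0.9 / 8192, t_period=0.9)
        beds = {1: _resistive_spectrum(0.0, sett.t_period, sett.steps_per_period)}
        solver = SASolver(net, sett, beds, probes=[(1, 0.2, "a"), (1, 0.8, "b")])
        pulse = lambda t: 2.0 * math.exp(-(((t - 0.01) / 0.003) ** 2))
        res, _ = run_sa(net, pulse, beds, 1, settings=sett, solver=solver)
        ta = res.t[np.argmax(res.probes["a"]["P"])]
        tb = res.t[np.argmax(res.probes["b"]["P"])]
        c_num = 0.6 * 100.0 / (tb - ta)
        c_ana = wave_speed(math.pi * 0.25, 0.5, law)
        assert c_num == pytest.approx(c_ana, rel=0.02)

    def test_causality_no_instant_distal_response(self):
        law = TubeLawParams()
        net = _single_vessel(law, length=60.0, r=0.5)
        sett = SolverSettings(dt=0.9 / 4096, t_period=0.9)
        beds = {1: _resistive_spectrum(50.0, sett.t_period, sett.steps_per_period)}
        solver = SASolver(net, sett, beds, probes=[(1, 0.9, "far")])
        c0 = wave_speed(math.pi * 0.25, 0.5, law)
        n_steps = 200
        reach_time = 0.9 * 60.0 / c0  # earliest arrival at the probe
        res, _ = run_sa(net, lambda t: 5.0, beds, 1, settings=sett, solver=solver)
        # well before the wave-front arrival the probe is strictly quiet
        # (the scheme's dispersive precursor only appears near the front)
        before = res.t < 0.6 * reach_time
        assert np.max(np.abs(res.probes["far"]["Q"][before])) < 1e-8

    def test_refinement_changes_pressures_under_one_percent(self):
        law = TubeLawParams()
        inflow = make_inflow(SV=30.0, Q_peak=200.0, t_ej=0.3, period=0.9)
        peaks = {}
        for N in (2048, 4096):
            sett = SolverSettings(dt=0.9 / N, t_period=0.9, cfl_build=0.3)
            net = _single_vessel(law, length=20.0, r=0.45)
            beds = {1: _resistive_spectrum(800.0, sett.t_period, sett.steps_per_period)}
            res, _ = run_sa(net, inflow, beds, 3, settings=sett)
            P = res.probes["v_mid"]["P"]
            n = sett.steps_per_period
            peaks[N] = (P[-n:].max(), P[-n:].min())
        assert peaks[2048][0] == pytest.approx(peaks[4096][0], rel=0.01)
        assert peaks[2048][1] == pytest.approx(peaks[4096][1], rel=0.01)

    def test_cfl_violation_reports_segment(self):
        net = _single_vessel()
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        beds = {1: _resistive_spectrum(10.0, sett.t_period, sett.steps_per_period)}
        solver = SASolver(net, sett, beds)
        solver.state.Q[1][:] = 1e4  # absurd velocity
        with pytest.raises(SolverError, match="CFL|supercritical"):
            solver.step(1e4)


class TestInletBC:
    def test_inflow_volume_conserved(self):
        # d/dt(stored volume) integrates the inflow exactly at a closed end
        net = _single_vessel(length=20.0, r=0.45)
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        inflow = make_inflow(SV=20.0, Q_peak=150.0, t_ej=0.25, period=0.9)
        beds = {1: _resistive_spectrum(1e7, sett.t_period, sett.steps_per_period)}
        solver = SASolver(net, sett, beds)
        g = solver.disc.grids[1]
        vol0 = float(np.trapezoid(solver.state.A[1], g.x))
        n = sett.steps_per_period
        res, solver = run_sa(net, inflow, beds, 1, settings=sett, solver=solver)
        vol1 = float(np.trapezoid(solver.state.A[1], g.x))
        out = np.sum(solver.hist[1]) * sett.dt  # leaked through the stiff terminal
        assert vol1 - vol0 + out == pytest.approx(inflow.SV, rel=0.005)

    def test_step_inflow_launches_forward_wave_only(self):
        net = _single_vessel(length=40.0, r=0.5)
        sett = SolverSettings(dt=0.9 / 4096, t_period=0.9)
        beds = {1: _resistive_spectrum(100.0, sett.t_period, sett.steps_per_period)}
        solver = SASolver(net, sett, beds, probes=[(1, 0.05, "near"), (1, 0.95, "far")])
        res, _ = run_sa(net, lambda t: 10.0, beds, 1, settings=sett, solver=solver)
        i_near = np.argmax(res.probes["near"]["Q"] > 1e-6)
        i_far = np.argmax(res.probes["far"]["Q"] > 1e-6)
        assert i_near < i_far


class TestJunctions:
    def test_symmetric_split(self):
        law = TubeLawParams()
        net = make_test_network("symmetric_bifurcation", law)
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        beds = terminal_impedances(net, TreeParams(), sett)
        inflow = make_inflow(SV=30.0, Q_peak=200.0, t_ej=0.3, period=0.9)
        res, solver = run_sa(net, inflow, beds, 2, settings=sett)
        Q2 = res.probes["daughter_a_mid"]["Q"]
        Q3 = res.probes["daughter_b_mid"]["Q"]
        assert np.allclose(Q2, Q3, rtol=0.0, atol=1e-10 * max(1.0, np.max(np.abs(Q2))))

    def test_flow_conservation_residual(self):
        net = make_test_network("symmetric_bifurcation")
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        beds = terminal_impedances(net, TreeParams(), sett)
        inflow = make_inflow(SV=30.0, Q_peak=200.0, t_ej=0.3, period=0.9)
        solver = SASolver(net, sett, beds, record=False)
        worst = 0.0
        for k in range(600):
            solver.step(float(inflow(solver.state.t + sett.dt)))
            qp = solver.state.Q[1][-1]
            qd = solver.state.Q[2][0] + solver.state.Q[3][0]
            if abs(qp) > 1e-8:
                worst = max(worst, abs(qp - qd) / abs(qp))
        assert worst < 1e-10

    def test_pressure_continuity_at_junction(self):
        net = make_test_network("symmetric_bifurcation")
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        beds = terminal_impedances(net, TreeParams(), sett)
        inflow = make_inflow(SV=30.0, Q_peak=200.0, t_ej=0.3, period=0.9)
        solver = SASolver(net, sett, beds, record=False)
        g1, g2 = solver.disc.grids[1], solver.disc.grids[2]
        for _ in range(500):
            solver.step(float(inflow(solver.state.t + sett.dt)))
        p_parent = g1.p_of(solver.state.A[1][-1], 1)
        p_daughter = g2.p_of(solver.state.A[2][0], 0)
        assert p_parent == pytest.approx(p_daughter, abs=1e-6 * abs(p_parent) + 1e-8)


class TestBoundaryOperations:
    def test_manual_step_matches_solver_step(self):
        # composing interior_step + junction_solve + terminal_bc + inlet_bc
        # reproduces the orchestrated solver exactly
        from lvsa.hemodynamics_solver import inlet_bc, junction_solve, terminal_bc

        net = make_test_network("symmetric_bifurcation")
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        beds = terminal_impedances(net, TreeParams(), sett)
        inflow = make_inflow(SV=30.0, Q_peak=200.0, t_ej=0.3, period=0.9)
        solver = SASolver(net, sett, beds, record=False)
        for _ in range(150):
            solver.step(float(inflow(solver.state.t + sett.dt)))
        old = solver.state.copy()
        hist = {k: v.copy() for k, v in solver.hist.items()}
        q_next = float(inflow(old.t + sett.dt))
        solver.step(q_next)
        new = interior_step(old, solver.disc)
        diag = junction_solve(new, old, solver.disc, 1)
        assert abs(diag["flow_residual"]) == 0.0
        for sid in (2, 3):
            terminal_bc(new, old, solver.disc, sid, beds[sid].z, hist[sid])
        inlet_bc(new, old, solver.disc, q_next)
        for sid in net.segments:
            assert np.array_equal(new.A[sid], solver.state.A[sid])
            assert np.array_equal(new.Q[sid], solver.state.Q[sid])


class TestTerminalBC:
    def test_resistive_terminal_is_ohmic(self):
        net = _single_vessel(length=15.0, r=0.45)
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        R = 700.0
        beds = {1: _resistive_spectrum(R, sett.t_period, sett.steps_per_period)}
        solver = SASolver(net, sett, beds, record=False)
        g = solver.disc.grids[1]
        for _ in range(3 * sett.steps_per_period):
            solver.step(8.0 * min(solver.state.t / 0.2, 1.0))
        P_T = g.p_of(solver.state.A[1][-1], 1) - g.law.P0
        Q_T = solver.state.Q[1][-1]
        assert P_T == pytest.approx(R * Q_T, rel=1e-6)

    def test_zero_flow_history_rest_pressure(self):
        law = TubeLawParams(P0=30 * MMHG)
        net = _single_vessel(law)
        beds = terminal_impedances(net, TreeParams(), SETT)
        solver = SASolver(net, SETT, beds)
        for _ in range(50):
            solver.step(0.0)
        g = solver.disc.grids[1]
        assert g.p_of(solver.state.A[1][-1], 1) == pytest.approx(law.P0)

    def test_steady_flow_reaches_dc_resistance(self):
        net = _single_vessel(length=10.0, r=0.4)
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        beds = terminal_impedances(net, TreeParams(), sett)
        q0 = 4.0
        solver = SASolver(net, sett, beds, record=False)
        for _ in range(8 * sett.steps_per_period):
            solver.step(q0 * min(solver.state.t / 0.3, 1.0))
        g = solver.disc.grids[1]
        P_T = g.p_of(solver.state.A[1][-1], 1) - g.law.P0
        assert P_T == pytest.approx(beds[1].dc_resistance * q0, rel=0.01)

    def test_missing_impedance_is_configuration_error(self):
        net = make_test_network("symmetric_bifurcation")
        with pytest.raises(ValueError, match="missing impedance"):
            SASolver(net, SETT, beds={})


class TestFrictionBalance:
    def test_steady_momentum_balance(self):
        # steady flow in a uniform vessel: dP/dx balances the friction term
        law = TubeLawParams()
        net = _single_vessel(law, length=30.0, r=0.35)
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        beds = {1: _resistive_spectrum(2000.0, sett.t_period, sett.steps_per_period)}
        solver = SASolver(net, sett, beds, record=False)
        q0 = 6.0
        for _ in range(6 * sett.steps_per_period):
            solver.step(q0 * min(solver.state.t / 0.3, 1.0))
        g = solver.disc.grids[1]
        A = solver.state.A[1]
        Q = solver.state.Q[1]
        P = g.law.P0 + g.f * (1.0 - np.sqrt(g.A0 / A))
        dPdx = np.gradient(P, g.x)
        R = np.sqrt(A / math.pi)
        fric = (2 * math.pi * law.nu * R / law.delta_star) * (Q / A)
        lhs = (A / law.rho) * dPdx
        interior = slice(4, -4)  # skip boundary-closure nodes
        assert np.allclose(lhs[interior], -fric[interior], rtol=0.01)


class TestRunSA:
    def test_zero_inflow_pressures_stay_at_p0(self):
        law = TubeLawParams(P0=40 * MMHG)
        net = make_test_network("symmetric_bifurcation", law)
        beds = terminal_impedances(net, TreeParams(), SETT)
        res, _ = run_sa(net, lambda t: 0.0, beds, 1, settings=SETT)
        for name in res.probes:
            assert np.allclose(res.probes[name]["P"], 40.0, atol=1e-9)

    def test_periodicity_and_volume_balance(self):
        net = make_test_network("symmetric_bifurcation")
        sett = SolverSettings(dt=0.9 / 2048, t_period=0.9)
        beds = terminal_impedances(net, TreeParams(), sett)
        inflow = make_inflow(SV=30.0, Q_peak=200.0, t_ej=0.3, period=0.9)
        res, solver = run_sa(net, inflow, beds, 6, settings=sett, record_terminals=True)
        N = sett.steps_per_period
        # consecutive-period pressure agreement < 1%
        for name in res.probes:
            P = res.probes[name]["P"]
            diff = np.max(np.abs(P[-N:] - P[-2 * N:-N])) / np.max(P[-N:])
            assert diff < 0.01
        # inflow volume = sum of terminal outflow volumes within 1%
        vin = np.sum(res.inflow[-N:]) * sett.dt
        vout = sum(
            np.sum(res.probes[f"{net.segments[sid].name}_outlet"]["Q"][-N:]) * sett.dt
            for sid in (2, 3)
        )
        assert vout == pytest.approx(vin, rel=0.01)
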