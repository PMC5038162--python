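"""Cardiac-cycle orchestration: valve phases and aortic-root exchange.

The chamber and the arterial network are coupled only while the aortic
valve is open.  Within each systolic arterial time step the interface flow
Q and pressure P are made mutually consistent: the network's inlet
characteristic maps a trial Q to an inlet pressure, the chamber maps the
implied volume change to a cavity pressure, and the exchanged state is the
root of the difference (a zero-pressure-drop valve).  The valve opens when
cavity pressure first reaches root pressure and closes when the solved
interface flow falls to zero.  Diastolic filling is a prescribed smooth
volume ramp back to the end-diastolic volume at the fixed end-diastolic
pressure (no mitral model), with the network running separately under zero
inflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .hemodynamics_solver import SASolver, SolverError
from .reduced_lv import ReducedLV
from .units import MMHG

__all__ = [
    "CouplingSettings",
    "CycleResult",
    "PeriodicRun",
    "run_phase_machine",
    "exchange_step",
    "interpolate_exchange",
    "run_until_periodic",
]

log = logging.getLogger(__name__)

_PHASE_CODES = {
    "isovolumetric_contraction": 0,
    "ejection": 1,
    "isovolumetric_relaxation": 2,
    "filling": 3,
}


@dataclass(frozen=True)
class CouplingSettings:
    """Exchange and convergence controls for the coupled run."""

    dt_lv: float = 1.22e-4
    systole_substep_factor: float = 0.125
    dt_sa: float = 0.9 / 8192
    exchange_tolerance: float = 1.0e-6
    max_exchange_iters: int = 60
    init_periods: int = 4
    convergence_threshold: float = 0.01
    edp_mmhg: float = 8.0
    q_max: float = 4000.0  # bracket ceiling for the interface flow (mL/s)
    #: blood-column inertance of the outflow tract, rho * l_eff / A_root
    #: (~1.055 g/cm^3 * 3 cm / 4.9 cm^2); makes ejection decelerate through
    #: zero flow while cavity pressure is still high, as in the 3D picture
    outflow_inertance: float = 0.65  # g cm^-4

    def __post_init__(self):
        if min(self.dt_lv, self.dt_sa, self.exchange_tolerance) <= 0:
            raise ValueError("time steps and tolerances must be positive")
        if not (0 < self.systole_substep_factor <= 1):
            raise ValueError("systole_substep_factor in (0, 1]")


@dataclass
class CycleResult:
    """One cardiac cycle of the coupled model, clinical units."""

    t: np.ndarray  # cycle-local time (s)
    V: np.ndarray  # LV cavity volume (mL)
    P_lv: np.ndarray  # LV cavity pressure (mmHg)
    Q_ao: np.ndarray  # interface (aortic-root) flow (mL/s)
    P_ao: np.ndarray  # interface pressure (mmHg)
    T_mean: np.ndarray  # wall-averaged active tension (kPa)
    phase: np.ndarray  # phase codes per step
    probes: dict  # per-probe {"P","Q","A"} over the cycle
    t_open: float | None
    t_close: float | None
    EDV: float
    ESV: float
    converged: bool = True

    @property
    def SV(self) -> float:
        """Stroke volume from the interface flow integral (mL)."""
        return float(np.trapezoid(self.Q_ao, self.t))

    @property
    def t_ej(self) -> float:
        if self.t_open is None or self.t_close is None:
            return 0.0
        return self.t_close - self.t_open


def interpolate_exchange(t_src, values, t_target):
    """Linear resampling of an exchange series; exact at shared grid points."""
    t_src = np.asarray(t_src, dtype=float)
    values = np.asarray(values, dtype=float)
    t_target = np.asarray(t_target, dtype=float)
    if np.any(t_target < t_src[0] - 1e-15) or np.any(t_target > t_src[-1] + 1e-15):
        raise ValueError("target times outside the source span (extrapolation)")
    out = np.interp(t_target, t_src, values)
    return float(out) if out.ndim == 0 else out


def exchange_step(
    lv: ReducedLV,
    sa: SASolver,
    V: float,
    q_prev: float,
    t_next: float,
    settings: CouplingSettings,
) -> tuple[float, float, float]:
    """Consistent interface (Q, P, V) for one systolic arterial step.

    The arterial step must have been prepared with ``sa.begin_step()``.
    Solves the momentum balance of the outflow-tract blood column,

        P_lv(V - (q_prev + Q) dt/2, t) - P_sa(Q) = L (Q - q_prev) / dt,

    for Q >= 0 by bracketed root finding (implicit Euler in the
    inertance, no transvalvular resistive drop); Q = 0 signals valve
    closure.  Returns (Q, P_interface_mmHg, V_new).
    """
    dt = sa.settings.dt
    L = settings.outflow_inertance

    def residual(q):
        v_try = max(V - 0.5 * (q_prev + q) * dt, 1e-3)
        p_lv = lv.pressure(v_try, t_next) * MMHG  # CGS
        return p_lv - sa.inlet_pressure_for(q) - L * (q - q_prev) / dt

    r0 = residual(0.0)
    if r0 <= 0.0:
        return 0.0, sa.inlet_pressure_for(0.0) / MMHG, V - 0.5 * q_prev * dt
    q_hi = max(2.0 * q_prev, 50.0)
    it = 0
    while residual(q_hi) > 0.0:
        q_hi *= 2.0
        it += 1
        if q_hi > settings.q_max:
            raise SolverError("interface flow bracket exceeded q_max")
    q = brentq(
        residual,
        0.0,
        q_hi,
        rtol=settings.exchange_tolerance,
        maxiter=settings.max_exchange_iters,
    )
    v_new = V - 0.5 * (q_prev + q) * dt
    return float(q), sa.inlet_pressure_for(q) / MMHG, float(v_new)


def run_phase_machine(
    lv: ReducedLV,
    sa: SASolver,
    settings: CouplingSettings,
    edv: float | None = None,
) -> CycleResult:
    """Run one full cardiac cycle on the solver's current arterial state.

    The cycle starts at the onset of isovolumetric contraction with the
    chamber filled to EDV at the fixed end-diastolic pressure, and runs
    for one arterial period: isovolumetric contraction -> ejection
    (coupled exchange) -> isovolumetric relaxation -> prescribed filling.
    """
    if edv is None:
        edv = lv.edv_at(settings.edp_mmhg)
    dt = sa.settings.dt
    n_steps = sa.settings.steps_per_period
    t_period = sa.settings.t_period
    t_twitch_end = lv.act.t_onset + lv.act.twitch_duration
    root = sa.net.root_id
    g_root = sa.disc.grids[root]

    phase = "isovolumetric_contraction"
    V = edv
    q_prev = 0.0
    t_open = t_close = None
    V_es = edv
    t_fill_start = t_twitch_end
    rec_start = len(sa._t_rec)
    t0_abs = sa.state.t

    out = {k: np.empty(n_steps) for k in ("t", "V", "P_lv", "Q_ao", "P_ao", "T_mean", "phase")}

    for i in range(n_steps):
        tau = (i + 1) * dt  # cycle-local time after this step
        sa.begin_step()
        if phase == "isovolumetric_contraction":
            p_lv = lv.pressure(V, tau)
            p_root = sa.inlet_pressure_for(0.0) / MMHG
            if p_lv >= p_root:
                phase = "ejection"
                t_open = tau
            elif tau >= t_twitch_end:
                # contraction too weak to open the valve
                phase = "filling"
                V_es = V
                t_fill_start = tau
        if phase == "ejection":
            q, p_ao, V = exchange_step(lv, sa, V, q_prev, tau, settings)
            sa.commit_step(q)
            if q == 0.0:
                phase = "isovolumetric_relaxation"
                t_close = tau
                V_es = V
                t_fill_start = max(t_twitch_end, t_close)
            q_prev = q
        else:
            if phase == "isovolumetric_relaxation" and tau >= t_fill_start:
                phase = "filling"
            if phase == "filling":
                span = t_period - t_fill_start
                u = min((tau - t_fill_start) / span, 1.0) if span > 0 else 1.0
                V = V_es + (edv - V_es) * 0.5 * (1.0 - np.cos(np.pi * u))
            sa.commit_step(0.0)
            q_prev = 0.0
        A_in = sa.state.A[root][0]
        out["t"][i] = tau
        out["V"][i] = V
        out["P_lv"][i] = lv.pressure(V, tau)
        out["Q_ao"][i] = sa.state.Q[root][0]
        out["P_ao"][i] = g_root.p_of(A_in, 0) / MMHG
        out["T_mean"][i] = lv.mean_tension(V, tau)
        out["phase"][i] = _PHASE_CODES[phase]

    if phase == "ejection":
        raise SolverError(
            "ejection phase did not terminate within the period "
            f"(t_open={t_open}, twitch_duration={lv.act.twitch_duration})"
        )
    probes = {}
    if sa.record:
        for name, rec in sa._records.items():
            probes[name] = {k: np.asarray(v[rec_start:]) for k, v in rec.items()}
    return CycleResult(
        t=out["t"],
        V=out["V"],
        P_lv=out["P_lv"],
        Q_ao=out["Q_ao"],
        P_ao=out["P_ao"],
        T_mean=out["T_mean"],
        phase=out["phase"],
        probes=probes,
        t_open=t_open,
        t_close=t_close,
        EDV=edv,
        ESV=V_es,
    )


@dataclass
class PeriodicRun:
    cycle_index: int  # index (1-based) of the first converged cycle
    result: CycleResult
    cycles: list = field(default_factory=list)
    converged: bool = True
    metric: float = np.nan
    metrics: list = field(default_factory=list)


def cycle_difference(a: CycleResult, b: CycleResult) -> float:
    """Max relative probe-pressure difference between two cycles."""
    worst = 0.0
    for name in b.probes:
        pa, pb = a.probes[name]["P"], b.probes[name]["P"]
        worst = max(worst, float(np.max(np.abs(pb - pa)) / np.max(np.abs(pb))))
    if not b.probes:
        worst = float(np.max(np.abs(b.P_ao - a.P_ao)) / np.max(np.abs(b.P_ao)))
    return worst


def run_until_periodic(
    lv: ReducedLV,
    sa: SASolver,
    settings: CouplingSettings,
    max_cycles: int = 8,
    min_cycles: int = 2,
) -> PeriodicRun:
    """Repeat coupled cycles until consecutive probe pressures agree.

    Convergence: max over probes and times of |P_n - P_{n-1}| / max P_n
    below ``settings.convergence_threshold``, checked from ``min_cycles``
    on.  If ``max_cycles`` is exhausted the best (last) cycle is returned
    with a warning flag.
    """
    if max_cycles < 2:
        raise ValueError("max_cycles >= 2")
    edv = lv.edv_at(settings.edp_mmhg)
    cycles = [run_phase_machine(lv, sa, settings, edv=edv)]
    metrics = []
    for n in range(1, max_cycles):
        cycles.append(run_phase_machine(lv, sa, settings, edv=edv))
        metric = cycle_difference(cycles[-2], cycles[-1])
        metrics.append(metric)
        log.info("cycle %d: periodicity metric %.3e", n + 1, metric)
        if n + 1 >= min_cycles and metric < settings.convergence_threshold:
            return PeriodicRun(
                cycle_index=n + 1,
                result=cycles[-1],
                cycles=cycles,
                converged=True,
                metric=metric,
                metrics=metrics,
            )
    warnings.warn(
        f"no periodic convergence within {max_cycles} cycles "
        f"(last metric {metrics[-1] if metrics else np.nan:.3e})",
        stacklevel=2,
    )
    last = cycles[-1]
    last.converged = False
    return PeriodicRun(
        cycle_index=max_cycles,
        result=last,
        cycles=cycles,
        converged=False,
        metric=metrics[-1] if metrics else np.nan,
        metrics=metrics,
    )
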