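"""Pathological scenarios, clinical index battery and elastance analysis.

Four scenarios modify the calibrated baseline one mechanism at a time:

* case1 - arterial stiffening: tube-law offset k3 doubled in the large
  arteries (vascular beds unchanged);
* case2 - vascular-bed rarefaction: radius exponent xi lowered from 2.76
  to 2.4, pruning the structured trees;
* case3 - stiffer myocardium: the a-type passive constants doubled;
* case4 - increased contractility: T0 raised by 33%.

``case1_iso`` / ``case2_iso`` apply the arterial changes to the isolated
network driven by the baseline inflow, to expose what the ventricular
feedback contributes.

The index battery covers chamber pump function (peak tension, peak
pressures, peak flow, stroke volume and work, ejection time, EF), probe
waveform indices (peaks, troughs, timing, backflow) and the
ventricular-arterial coupling measures E_A (end-systolic pressure over
stroke volume) and E_S (slope of the end-systolic pressure-volume
relation fitted through baseline, case1 and case2).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coupling_engine import (
    CouplingSettings,
    CycleResult,
    PeriodicRun,
    run_phase_machine,
    run_until_periodic,
)
from .hemodynamics_solver import (
    SASolver,
    SimulationResult,
    SolverSettings,
    run_sa,
    terminal_impedances,
)
from .io_fixtures import RunConfig
from .reduced_lv import ReducedLV, calibrate_baseline
from .units import MMHG_ML_TO_CJ

__all__ = [
    "CaseSpec",
    "IndexReport",
    "apply_case",
    "lv_indices",
    "waveform_indices",
    "elastances",
    "compare_to_baseline",
    "CaseRun",
    "simulate_case",
    "calibrate_config",
    "build_sa",
    "initialize_sa",
    "coupling_settings",
]

log = logging.getLogger(__name__)

CASE_IDS = ("baseline", "case1", "case2", "case3", "case4", "case1_iso", "case2_iso")


@dataclass(frozen=True)
class CaseSpec:
    """Named scenario and its parameter modifications."""

    case_id: str
    description: str
    iso_flag: bool = False

    @classmethod
    def from_id(cls, case_id: str) -> "CaseSpec":
        desc = {
            "baseline": "calibrated healthy baseline",
            "case1": "arterial stiffening: k3 x2 in the large arteries",
            "case2": "vascular-bed rarefaction: xi 2.76 -> 2.4",
            "case3": "stiffer myocardium: a-type constants x2",
            "case4": "increased contractility: T0 x1.33",
            "case1_iso": "case1 arteries, isolated network, baseline inflow",
            "case2_iso": "case2 arteries, isolated network, baseline inflow",
        }
        if case_id not in desc:
            raise ValueError(f"unknown case id {case_id!r}; expected one of {CASE_IDS}")
        return cls(case_id, desc[case_id], iso_flag=case_id.endswith("_iso"))


def apply_case(config: RunConfig, case_id: str) -> RunConfig:
    """Return a copy of ``config`` with the scenario's modifications."""
    spec = CaseSpec.from_id(case_id)
    cfg = dataclasses.replace(config, case_id=case_id)
    base = case_id.replace("_iso", "")
    if base == "case1":
        # stiffen large arteries only: beds keep the baseline wall law
        cfg.bed_tube_law = config.bed_wall_law()
        cfg.tube_law = replace(config.tube_law, k3=2.0 * config.tube_law.k3)
    elif base == "case2":
        cfg.tree = replace(config.tree, xi=2.4)
    elif base == "case3":
        cfg.ho = replace(config.ho, stiffness_scale=2.0 * config.ho.stiffness_scale)
    elif base == "case4":
        cfg.act = replace(config.act, T0=1.33 * config.act.T0)
    elif base != "baseline":
        raise ValueError(f"unknown case id {case_id!r}")
    return cfg


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------


@dataclass
class IndexReport:
    """Clinical index battery of one converged run."""

    Tpeak_kPa: float = np.nan
    Ppeak_ao_mmHg: float = np.nan
    Ppeak_LV_mmHg: float = np.nan
    Qpeak_ao_mL_s: float = np.nan
    SV_mL: float = np.nan
    SW_cJ: float = np.nan
    t_ej_ms: float = np.nan
    EF: float = np.nan
    EDV_mL: float = np.nan
    ESV_mL: float = np.nan
    P_es_mmHg: float = np.nan
    V_es_mL: float = np.nan
    EA_mmHg_per_mL: float = np.nan
    probes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "probes"}
        return d


def _loop_area(V: np.ndarray, P: np.ndarray) -> float:
    """Absolute shoelace area of the closed (V, P) loop (mmHg*mL).

    Invariant to where along the loop the cycle starts.
    """
    v2 = np.append(V, V[0])
    p2 = np.append(P, P[0])
    return float(abs(0.5 * np.sum(v2[:-1] * p2[1:] - v2[1:] * p2[:-1])))


def lv_indices(cycle: CycleResult, require_converged: bool = True) -> IndexReport:
    """Pump-function indices of one cardiac cycle."""
    if require_converged and not cycle.converged:
        raise ValueError("cycle is not flagged as periodic; pass require_converged=False")
    sv = cycle.SV
    sw = _loop_area(cycle.V, cycle.P_lv) * MMHG_ML_TO_CJ
    if cycle.t_close is not None:
        i_es = int(np.searchsorted(cycle.t, cycle.t_close))
        i_es = min(i_es, len(cycle.t) - 1)
        p_es = float(cycle.P_lv[i_es])
        v_es = float(cycle.V[i_es])
    else:
        p_es, v_es = np.nan, float(cycle.ESV)
        sv, sw = 0.0, 0.0
    rep = IndexReport(
        Tpeak_kPa=float(np.max(cycle.T_mean)),
        Ppeak_ao_mmHg=float(np.max(cycle.P_ao)),
        Ppeak_LV_mmHg=float(np.max(cycle.P_lv)),
        Qpeak_ao_mL_s=float(np.max(cycle.Q_ao)),
        SV_mL=sv,
        SW_cJ=sw,
        t_ej_ms=cycle.t_ej * 1e3,
        EF=sv / cycle.EDV,
        EDV_mL=cycle.EDV,
        ESV_mL=float(cycle.ESV),
        P_es_mmHg=p_es,
        V_es_mL=v_es,
        EA_mmHg_per_mL=(p_es / sv) if sv > 0 else np.nan,
    )
    for name, series in cycle.probes.items():
        rep.probes[name] = waveform_indices(cycle.t, series["P"], series["Q"])
    return rep


def waveform_indices(t, P, Q) -> dict:
    """Peak/trough/timing indices of one probe over one period.

    Peak times use the earliest attaining sample (documented tie-break);
    backflow is the magnitude of the most negative flow, clipped at 0.
    """
    t = np.asarray(t, dtype=float)
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    ip = int(np.argmax(P))
    iq = int(np.argmax(Q))
    return {
        "P_peak": float(P[ip]),
        "P_trough": float(np.min(P)),
        "t_peak": float(t[ip] - t[0]),
        "Q_peak": float(Q[iq]),
        "t_Q_peak": float(t[iq] - t[0]),
        "Q_max_back": float(max(0.0, -np.min(Q))),
    }


def elastances(runs: dict[str, IndexReport]) -> dict:
    """Ventricular-arterial coupling indices from three coupled runs.

    ``runs`` must hold IndexReports for baseline, case1 and case2 (same
    contractility).  E_A = P_es / SV per run; E_S is the least-squares
    slope through the three end-systolic (V, P) points; the ratio
    E_A/E_S is reported per run.
    """
    for key in ("baseline", "case1", "case2"):
        if key not in runs:
            raise ValueError(f"elastances needs a {key!r} run")
    V = np.array([runs[k].V_es_mL for k in ("baseline", "case1", "case2")])
    P = np.array([runs[k].P_es_mmHg for k in ("baseline", "case1", "case2")])
    if np.ptp(V) < 1e-9:
        raise ValueError("end-systolic volumes are degenerate; ESPVR slope undefined")
    slope, _ = np.polyfit(V, P, 1)
    ea = {k: runs[k].EA_mmHg_per_mL for k in runs}
    return {
        "EA": ea,
        "ES": float(slope),
        "EA_over_ES": {k: v / slope for k, v in ea.items()},
        "es_points": {"V": V.tolist(), "P": P.tolist()},
    }


_DELTA_FIELDS = [
    "Tpeak_kPa",
    "Ppeak_ao_mmHg",
    "Ppeak_LV_mmHg",
    "Qpeak_ao_mL_s",
    "SV_mL",
    "SW_cJ",
    "t_ej_ms",
    "EF",
]


def compare_to_baseline(reports: dict[str, IndexReport]) -> pd.DataFrame:
    """Percent changes of every numeric index relative to the baseline."""
    if "baseline" not in reports:
        raise ValueError("baseline report required")
    base = reports["baseline"]
    rows = {}
    for case, rep in reports.items():
        if case == "baseline":
            continue
        row = {}
        for f_ in _DELTA_FIELDS:
            b = getattr(base, f_)
            v = getattr(rep, f_)
            row[f_] = 100.0 * (v - b) / b if b not in (0.0,) and np.isfinite(b) else np.nan
        rows[case] = row
    df = pd.DataFrame(rows).T
    return df.round(1)


# ---------------------------------------------------------------------------
# run pipeline
# ---------------------------------------------------------------------------


@dataclass
class CaseRun:
    """Everything produced by one scenario run."""

    config: RunConfig
    cycle: CycleResult | None  # coupled runs
    sa_result: SimulationResult | None  # iso runs
    report: IndexReport
    periodic: PeriodicRun | None = None


def _build_sa(config: RunConfig, probes=None, record=True):
    if probes is None:
        probes = config.probes
    net = config.network()
    settings = SolverSettings(dt=config.dt, t_period=config.t_period)
    beds = terminal_impedances(net, config.tree, settings, wall_law=config.bed_wall_law())
    solver = SASolver(net, settings, beds, probes=probes, record=record)
    return net, settings, beds, solver


def _init_solver(config: RunConfig, solver: SASolver, inflow=None) -> None:
    """Flush transients with the prescribed inflow for the init periods."""
    inflow = inflow if inflow is not None else config.init_inflow()
    n = solver.settings.steps_per_period * config.init_periods
    for _ in range(n):
        solver.step(float(inflow(solver.state.t + solver.settings.dt)))


def _coupling_settings(config: RunConfig) -> CouplingSettings:
    return CouplingSettings(
        dt_sa=config.dt,
        exchange_tolerance=config.exchange_tolerance,
        init_periods=config.init_periods,
        convergence_threshold=config.convergence_threshold,
        edp_mmhg=config.edp_mmhg,
    )


# public names for the run-assembly helpers
def build_sa(config: RunConfig, probes=None, record=True):
    """Network, solver settings, bed impedances and a fresh solver."""
    return _build_sa(config, probes=probes, record=record)


def initialize_sa(config: RunConfig, solver: SASolver, inflow=None) -> None:
    """Run the prescribed-inflow initialization periods on ``solver``."""
    _init_solver(config, solver, inflow=inflow)


def coupling_settings(config: RunConfig) -> CouplingSettings:
    return _coupling_settings(config)


def calibrate_config(config: RunConfig, solver: SASolver | None = None) -> tuple[RunConfig, dict]:
    """Calibrate the chamber to the configured EDV/SV/ejection-time targets.

    Runs the passive scale fit and the coupled T0/twitch search against a
    warm arterial state (initialized here if no solver is given).
    Returns the calibrated config and the calibration report.
    """
    if solver is None:
        _, _, _, solver = _build_sa(config, record=False)
        _init_solver(config, solver)
    snap_state = solver.state.copy()
    snap_hist = {k: v.copy() for k, v in solver.hist.items()}
    prev_record = solver.record
    cset = _coupling_settings(config)

    def cycle_runner(hop, actp):
        solver.state = snap_state.copy()
        solver.hist = {k: v.copy() for k, v in snap_hist.items()}
        solver.record = False
        lv = ReducedLV(config.geom, hop, actp)
        edv = lv.edv_at(cset.edp_mmhg)
        run_phase_machine(lv, solver, cset, edv=edv)
        cyc = run_phase_machine(lv, solver, cset, edv=edv)
        return cyc.SV, cyc.t_ej

    ho, act, report = calibrate_baseline(
        config.targets, config.geom, config.ho, config.act, cycle_runner,
        edp_mmhg=config.edp_mmhg,
    )
    solver.state = snap_state
    solver.hist = snap_hist
    solver.record = prev_record
    cfg = dataclasses.replace(config, ho=ho, act=act)
    log.info("calibration report: %s", report)
    return cfg, report


def simulate_case(
    config: RunConfig,
    baseline_inflow=None,
    warm_solver: SASolver | None = None,
) -> CaseRun:
    """Run one scenario to periodicity and compute its index battery.

    Coupled scenarios run the phase machine after the prescribed-inflow
    initialization; isolated scenarios keep the prescribed inflow (pass
    the baseline coupled interface flow as ``baseline_inflow``) and build
    the report from the last arterial period.
    """
    spec = CaseSpec.from_id(config.case_id)
    if warm_solver is None:
        net, settings, beds, solver = _build_sa(config)
        _init_solver(config, solver, inflow=baseline_inflow if spec.iso_flag else None)
    else:
        solver = warm_solver
        settings = solver.settings
    cset = _coupling_settings(config)

    if spec.iso_flag:
        if baseline_inflow is None:
            raise ValueError("isolated runs need the baseline inflow waveform")
        N = settings.steps_per_period
        res = None
        for _ in range(config.max_cycles):
            res, solver = run_sa(
                solver.net, baseline_inflow, solver.beds, 1, settings=settings, solver=solver
            )
            if len(res.t) >= 2 * N:
                prev = {n: res.probes[n]["P"][-2 * N:-N] for n in res.probes}
                cur = {n: res.probes[n]["P"][-N:] for n in res.probes}
                metric = max(
                    float(np.max(np.abs(cur[n] - prev[n])) / np.max(np.abs(cur[n])))
                    for n in cur
                )
                if metric < config.convergence_threshold:
                    break
        rep = IndexReport()
        tlast = res.t[-N:]
        for name, series in res.probes.items():
            rep.probes[name] = waveform_indices(
                tlast, series["P"][-N:], series["Q"][-N:]
            )
        return CaseRun(config=config, cycle=None, sa_result=res, report=rep)

    lv = ReducedLV(config.geom, config.ho, config.act)
    periodic = run_until_periodic(lv, solver, cset, max_cycles=config.max_cycles)
    rep = lv_indices(periodic.result, require_converged=False)
    return CaseRun(
        config=config,
        cycle=periodic.result,
        sa_result=None,
        report=rep,
        periodic=periodic,
    )
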