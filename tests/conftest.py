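"""Shared fixtures.

``study`` is the expensive session fixture: the calibrated baseline
coupled run plus the four pathological scenarios and the two isolated
network runs, all at the scaled-down resolution (2048 steps/period).
Everything else is cheap and deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvsa.coupling_engine import run_until_periodic
from lvsa.io_fixtures import RunConfig
from lvsa.reduced_lv import ReducedLV
from lvsa.scenarios_indices import (
    _build_sa,
    _coupling_settings,
    _init_solver,
    apply_case,
    calibrate_config,
    lv_indices,
    simulate_case,
)
from lvsa.structured_tree import TreeParams


def default_probe_list(net):
    """Midpoints of every segment plus terminal outlets and the root inlet."""
    probes = [(sid, 0.5, f"{net.segments[sid].name}_mid") for sid in sorted(net.segments)]
    probes += [
        (sid, 1.0, f"{net.segments[sid].name}_outlet")
        for sid in sorted(net.segments)
        if net.segments[sid].is_terminal
    ]
    probes.append((net.root_id, 0.0, "root_inlet"))
    return probes


@pytest.fixture(scope="session")
def study():
    """Calibrated baseline + scenarios at the scaled-down resolution."""
    cfg = RunConfig()
    net = cfg.network()
    _, settings, beds, solver = _build_sa(cfg, probes=default_probe_list(net))
    _init_solver(cfg, solver)
    cal_cfg, cal_report = calibrate_config(cfg, solver=solver)
    lv = ReducedLV(cal_cfg.geom, cal_cfg.ho, cal_cfg.act)
    periodic = run_until_periodic(
        lv, solver, _coupling_settings(cal_cfg), max_cycles=8, min_cycles=3
    )
    baseline_rep = lv_indices(periodic.result, require_converged=False)
    cyc = periodic.result

    def baseline_inflow(t):
        return float(np.interp(np.mod(t, cfg.t_period), cyc.t, cyc.Q_ao))

    runs = {"baseline": None}
    reports = {"baseline": baseline_rep}
    for case in ("case1", "case2", "case3", "case4"):
        ccfg = apply_case(cal_cfg, case)
        run = simulate_case(ccfg)
        runs[case] = run
        reports[case] = run.report
    iso_reports = {}
    for case in ("case1_iso", "case2_iso"):
        ccfg = apply_case(cal_cfg, case)
        run = simulate_case(ccfg, baseline_inflow=baseline_inflow)
        iso_reports[case] = run.report
    return {
        "cfg": cfg,
        "cal_cfg": cal_cfg,
        "cal_report": cal_report,
        "periodic": periodic,
        "cycle": cyc,
        "baseline": baseline_rep,
        "reports": reports,
        "runs": runs,
        "iso_reports": iso_reports,
        "net": net,
    }


@pytest.fixture
def tree_params():
    return TreeParams()
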