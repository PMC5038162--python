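"""Configuration, run I/O, inflow waveforms and test-network generators.

Everything the simulator consumes can be generated here deterministically:
no external data are required.  Results are written as diff-able CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import quad
from scipy.optimize import brentq

from . import __version__ as _pkg_version
from .network_model import (
    ArterialNetwork,
    TubeLawParams,
    VesselSegment,
    default24,
    load_network_csv,
)
from .structured_tree import TreeParams
from .reduced_lv import ActivationParams, ChamberGeometry, HOParams
from .units import MMHG

__all__ = [
    "InflowWaveform",
    "make_inflow",
    "make_test_network",
    "RunConfig",
    "write_run",
    "read_run",
]


# ---------------------------------------------------------------------------
# inflow waveform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InflowWaveform:
    """Parametric systolic inflow pulse q(t) = Q_peak sin^p(pi t / t_ej).

    Non-negative, zero in diastole, exact peak Q_peak, and the exponent p
    is solved so the period integral equals SV.
    """

    SV: float  # mL
    Q_peak: float  # mL/s
    t_ej: float  # s
    period: float  # s
    p_exponent: float

    def __call__(self, t):
        tau = np.mod(np.asarray(t, dtype=float), self.period)
        out = np.zeros_like(tau)
        inside = tau < self.t_ej
        out[inside] = self.Q_peak * np.sin(math.pi * tau[inside] / self.t_ej) ** self.p_exponent
        return float(out) if out.ndim == 0 else out

    def samples(self, n: int) -> np.ndarray:
        return self(np.arange(n) * self.period / n)

    @property
    def integral(self) -> float:
        val, _ = quad(lambda s: math.sin(math.pi * s) ** self.p_exponent, 0.0, 1.0)
        return self.Q_peak * self.t_ej * val


def make_inflow(SV: float, Q_peak: float, t_ej: float, period: float) -> InflowWaveform:
    """Build the sin^p systolic pulse matching SV, Q_peak and t_ej.

    At SV = Q_peak * t_ej / 2 the shape degenerates to the squared sine.
    """
    if min(SV, Q_peak, t_ej, period) <= 0:
        raise ValueError("all waveform parameters must be positive")
    if t_ej > period:
        raise ValueError("ejection time exceeds the period")
    ratio = SV / (Q_peak * t_ej)

    def shape_integral(p):
        val, _ = quad(lambda s: math.sin(math.pi * s) ** p, 0.0, 1.0)
        return val

    lo, hi = 0.05, 60.0
    if not (shape_integral(hi) < ratio < shape_integral(lo)):
        raise ValueError(
            f"infeasible SV/Q_peak/t_ej combination: need SV/(Q_peak*t_ej) in "
            f"({shape_integral(hi):.3f}, {shape_integral(lo):.3f}), got {ratio:.3f}"
        )
    p = brentq(lambda q: shape_integral(q) - ratio, lo, hi, xtol=1e-12)
    return InflowWaveform(SV=SV, Q_peak=Q_peak, t_ej=t_ej, period=period, p_exponent=p)


# ---------------------------------------------------------------------------
# test networks
# ---------------------------------------------------------------------------


def make_test_network(kind: str, tube_law: TubeLawParams | None = None) -> ArterialNetwork:
    """Deterministic fixture networks.

    single_vessel         one terminal segment with a bed
    symmetric_bifurcation parent feeding two identical terminal daughters
    default24             the shipped 24-artery tree
    """
    if kind == "single_vessel":
        segs = [
            VesselSegment(
                id=1, name="vessel", length=12.0, r_top=0.4, r_bottom=0.4,
                bed_root_radius=0.4,
            )
        ]
        return ArterialNetwork(segs, 1, tube_law)
    if kind == "symmetric_bifurcation":
        segs = [
            VesselSegment(id=1, name="parent", length=8.0, r_top=0.5, r_bottom=0.5,
                          daughters=(2, 3)),
            VesselSegment(id=2, name="daughter_a", length=8.0, r_top=0.35,
                          r_bottom=0.35, bed_root_radius=0.35),
            VesselSegment(id=3, name="daughter_b", length=8.0, r_top=0.35,
                          r_bottom=0.35, bed_root_radius=0.35),
        ]
        return ArterialNetwork(segs, 1, tube_law)
    if kind == "default24":
        return default24(tube_law)
    raise ValueError(f"unknown test network kind {kind!r}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Aggregate configuration of a simulation run.

    The default instance reproduces the baseline study conditions: the
    24-artery tree, structured-tree beds (xi = 2.76, asymmetry 0.41,
    r_min = 100 um), the chamber calibrated around EDV 142.4 mL / SV
    72.6 mL / ejection 220 ms at EDP 8 mmHg, period 0.9 s.  The external
    pressure p0 = 50 mmHg is the documented DC-balance choice (mean
    pressure = p0 + R_dc * CO at normal MAP).
    """

    network_path: str | None = None
    p0_mmhg: float = 50.0
    tube_law: TubeLawParams = field(default_factory=TubeLawParams)
    tree: TreeParams = field(default_factory=TreeParams)
    bed_tube_law: TubeLawParams | None = None  # wall law of the small vessels
    geom: ChamberGeometry = field(default_factory=ChamberGeometry)
    ho: HOParams = field(default_factory=HOParams)
    act: ActivationParams = field(default_factory=ActivationParams)
    t_period: float = 0.9
    n_steps: int = 2048
    init_periods: int = 4
    max_cycles: int = 8
    convergence_threshold: float = 0.01
    exchange_tolerance: float = 1.0e-6
    edp_mmhg: float = 8.0
    case_id: str = "baseline"
    targets: dict = field(
        default_factory=lambda: {"EDV": 142.4, "SV": 72.6, "t_ej": 0.220}
    )
    inflow: dict = field(
        default_factory=lambda: {"SV": 72.6, "Q_peak": 500.0, "t_ej": 0.30}
    )
    probes: list | None = None  # None -> midpoint of every segment
    decimation: int = 1

    def __post_init__(self):
        if self.p0_mmhg and self.tube_law.P0 == 0.0:
            self.tube_law = replace(self.tube_law, P0=self.p0_mmhg * MMHG)

    @property
    def dt(self) -> float:
        return self.t_period / self.n_steps

    def network(self) -> ArterialNetwork:
        if self.network_path is None:
            return default24(self.tube_law)
        return load_network_csv(self.network_path, self.tube_law)

    def bed_wall_law(self) -> TubeLawParams:
        """Wall law of the structured-tree vessels.

        Defaults to the large-artery law; kept separate so scenarios that
        stiffen only the large arteries leave the beds untouched.
        """
        return self.bed_tube_law if self.bed_tube_law is not None else self.tube_law

    def init_inflow(self) -> InflowWaveform:
        return make_inflow(
            SV=self.inflow["SV"],
            Q_peak=self.inflow["Q_peak"],
            t_ej=self.inflow["t_ej"],
            period=self.t_period,
        )

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("tube_law", TubeLawParams),
            ("tree", TreeParams),
            ("geom", ChamberGeometry),
            ("ho", HOParams),
            ("act", ActivationParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if d.get("bed_tube_law") is not None and isinstance(d["bed_tube_law"], dict):
            d["bed_tube_law"] = TubeLawParams(**d["bed_tube_law"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run directory I/O
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def write_run(result, path, config: RunConfig | None = None, decimation: int = 1) -> None:
    """Write a simulation result as per-probe CSVs plus a JSON manifest.

    ``result`` needs attributes ``t`` (s) and ``probes`` (name -> dict of
    arrays with keys P, Q, A in mmHg, mL/s, cm^2), plus optional
    ``meta``.  Decimation keeps every k-th sample including both
    endpoints.
    """
    if decimation < 1:
        raise ValueError("decimation factor must be >= 1")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    idx = np.arange(0, len(result.t), decimation)
    if idx[-1] != len(result.t) - 1:
        idx = np.append(idx, len(result.t) - 1)
    files = {}
    for name, series in result.probes.items():
        df = pd.DataFrame(
            {
                "t_s": result.t[idx],
                "P_mmHg": series["P"][idx],
                "Q_mL_per_s": series["Q"][idx],
                "A_cm2": series["A"][idx],
            }
        )
        fname = f"probe_{name}.csv"
        df.to_csv(path / fname, index=False)  # shortest round-trip float repr
        files[name] = fname
    manifest = {
        "schema_version": _SCHEMA_VERSION,
        "package_version": _pkg_version,
        "files": files,
        "decimation": decimation,
        "n_samples": int(len(idx)),
        "meta": getattr(result, "meta", {}),
    }
    if config is not None:
        manifest["case_id"] = config.case_id
        manifest["config_hash"] = config.config_hash()
        config.to_yaml(path / "config.yaml")
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)


class LoadedRun:
    def __init__(self, t, probes, manifest):
        self.t = t
        self.probes = probes
        self.manifest = manifest
        self.meta = manifest.get("meta", {})


def read_run(path) -> LoadedRun:
    """Read back a run directory written by :func:`write_run`."""
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(
            f"unsupported run schema {manifest.get('schema_version')!r}; "
            f"expected {_SCHEMA_VERSION}"
        )
    probes = {}
    t = None
    for name, fname in manifest["files"].items():
        df = pd.read_csv(path / fname, float_precision="round_trip")
        t = df["t_s"].to_numpy()
        probes[name] = {
            "P": df["P_mmHg"].to_numpy(),
            "Q": df["Q_mL_per_s"].to_numpy(),
            "A": df["A_cm2"].to_numpy(),
        }
    return LoadedRun(t, probes, manifest)
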