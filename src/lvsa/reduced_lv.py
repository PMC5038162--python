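"""Reduced-order contracting left ventricle.

The chamber is an incompressible thick-walled sphere.  The myocardium
carries the Holzapfel-Ogden passive response, evaluated for the
equibiaxial tangent-plane kinematics of a sphere wall
(lambda_theta = lambda_phi = lam, lambda_r = lam^-2) with fibers (and
sheets) uniformly distributed in the tangent plane, plus an active fiber
tension T0 * twitch(t) * length-factor driven by a prescribed normalized
activation transient.  Cavity pressure follows from radial equilibrium,

    P = int_{ri}^{ro} (sigma_tt + sigma_pp - 2 sigma_rr) / r dr,

with the shell radii mapped incompressibly from the unloaded geometry.
This keeps the passive-stiffness constants and T0 as the physiological
knobs (stiffer myocardium, higher contractility) in a closed, testable
equilibrium, standing in for a full 3D fluid-structure model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

__all__ = [
    "HOParams",
    "ActivationParams",
    "ChamberGeometry",
    "LVState",
    "ReducedLV",
    "activation",
    "twitch",
    "ho_passive_stress",
    "cavity_pressure",
    "passive_inflate",
    "calibrate_baseline",
]

KPA_TO_MMHG = 7.50062

#: cavity phases of the valve state machine
PHASES = ("filling", "isovolumetric_contraction", "ejection", "isovolumetric_relaxation")


@dataclass(frozen=True)
class HOParams:
    """Holzapfel-Ogden constants (a-type in kPa, b-type dimensionless).

    ``stiffness_scale`` multiplies the a-type constants (a, af, as_, afs);
    it is both the passive calibration knob and the handle for the
    stiffer-myocardium scenario (x2).
    """

    a: float = 0.059
    b: float = 8.023
    af: float = 18.472
    bf: float = 16.026
    as_: float = 2.481
    bs: float = 11.120
    afs: float = 0.216
    bfs: float = 11.436
    stiffness_scale: float = 1.0

    def __post_init__(self):
        for name in ("a", "b", "af", "bf", "as_", "bs", "afs", "bfs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.stiffness_scale <= 0:
            raise ValueError("stiffness_scale must be > 0")


@dataclass(frozen=True)
class ActivationParams:
    """Phenomenological twitch parameters.

    T0 (kPa) scales the contraction; the twitch is a smooth unimodal
    pulse on [t_onset, t_onset + twitch_duration] with unit peak, the
    product of a rising and a falling exponential saturation.
    ``beta_length`` is the slope of the linear length-dependence factor
    max(0, 1 + beta_length (lam - 1)).
    """

    T0: float = 60.0
    t_onset: float = 0.0
    tau_rise: float = 0.12
    tau_fall: float = 0.06
    twitch_duration: float = 0.42
    beta_length: float = 7.0

    def __post_init__(self):
        if self.T0 < 0:
            raise ValueError("T0 must be >= 0")
        if min(self.tau_rise, self.tau_fall, self.twitch_duration) <= 0:
            raise ValueError("time constants must be > 0")


_TWITCH_PEAK_CACHE: dict[tuple[float, float, float], float] = {}


def _twitch_raw(tau, p: ActivationParams):
    tau = np.asarray(tau, dtype=float)
    inside = (tau > 0.0) & (tau < p.twitch_duration)
    out = np.zeros_like(tau)
    ti = tau[inside]
    out[inside] = (1.0 - np.exp(-ti / p.tau_rise)) * (
        1.0 - np.exp(-(p.twitch_duration - ti) / p.tau_fall)
    )
    return out


def twitch(t, p: ActivationParams):
    """Normalized activation transient: 0 outside the twitch, peak 1."""
    key = (p.tau_rise, p.tau_fall, p.twitch_duration)
    peak = _TWITCH_PEAK_CACHE.get(key)
    if peak is None:
        grid = np.linspace(0.0, p.twitch_duration, 4001)
        peak = float(_twitch_raw(grid, p).max())
        _TWITCH_PEAK_CACHE[key] = peak
    out = _twitch_raw(np.asarray(t, dtype=float) - p.t_onset, p) / peak
    return float(out) if out.ndim == 0 else out


def activation(t, lam, p: ActivationParams):
    """Active fiber tension T0 * twitch(t) * length factor (kPa)."""
    lf = np.maximum(0.0, 1.0 + p.beta_length * (np.asarray(lam, dtype=float) - 1.0))
    out = p.T0 * twitch(t, p) * lf
    return float(out) if np.ndim(out) == 0 else out


def ho_passive_stress(lam, p: HOParams):
    """In-plane minus radial Cauchy stress difference (kPa) at stretch lam.

    Equibiaxial incompressible state: I1 = 2 lam^2 + lam^-4, in-plane
    I4 = lam^2 for fibers and sheets (uniform tangent-plane distribution
    averages the cos^2 projection to 1/2); the I8fs shear term drops out
    in this kinematics.  Zero at lam = 1; fiber terms only engage in
    extension (I4 > 1).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    s = p.stiffness_scale
    lam2 = lam**2
    I1 = 2.0 * lam2 + lam ** (-4)
    iso = s * p.a * np.exp(p.b * (I1 - 3.0)) * (lam2 - lam ** (-4))
    e4 = np.maximum(lam2 - 1.0, 0.0)
    fib = s * p.af * e4 * np.exp(p.bf * e4**2)
    sht = s * p.as_ * e4 * np.exp(p.bs * e4**2)
    out = iso + (fib + sht) * lam2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ChamberGeometry:
    """Unloaded thick-shell geometry (cm); wall volume is conserved."""

    Ri: float = 2.70
    Ro: float = 3.758

    def __post_init__(self):
        if not (0 < self.Ri < self.Ro):
            raise ValueError("need 0 < Ri < Ro")

    @property
    def wall_volume(self) -> float:
        return 4.0 * math.pi / 3.0 * (self.Ro**3 - self.Ri**3)

    @property
    def unloaded_cavity_volume(self) -> float:
        return 4.0 * math.pi / 3.0 * self.Ri**3


@dataclass
class LVState:
    V: float  # mL
    P: float  # mmHg
    phase: str
    t: float  # s

    def __post_init__(self):
        if self.V <= 0:
            raise ValueError("cavity volume must be positive")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


_GAUSS_N = 64
_GX, _GW = leggauss(_GAUSS_N)


def _wall_quadrature(V: float, geom: ChamberGeometry):
    """Gauss nodes across the deformed wall for cavity volume V (mL).

    Returns (r, lam, weights*dr) with the unloaded radius R mapped
    incompressibly: r(R)^3 = ri^3 + R^3 - Ri^3.
    """
    ri3 = 3.0 * V / (4.0 * math.pi)
    R = 0.5 * (geom.Ro + geom.Ri) + 0.5 * (geom.Ro - geom.Ri) * _GX
    wR = 0.5 * (geom.Ro - geom.Ri) * _GW
    r3 = ri3 + R**3 - geom.Ri**3
    r = np.cbrt(r3)
    lam = r / R
    # dr = (R^2 / r^2) dR
    return r, lam, wR * R**2 / r**2


def cavity_pressure(
    V: float,
    t: float,
    geom: ChamberGeometry,
    hop: HOParams,
    actp: ActivationParams | None = None,
) -> float:
    """Quasi-static cavity pressure (mmHg) at volume V (mL) and time t (s).

    Radial equilibrium of the incompressible spherical shell integrated
    with 64-point Gauss quadrature; active tension acts along the
    in-plane distributed fiber field, contributing T to
    sigma_tt + sigma_pp - 2 sigma_rr.
    """
    if V <= 0:
        raise ValueError("cavity volume must be positive")
    r, lam, w = _wall_quadrature(V, geom)
    integrand = 2.0 * ho_passive_stress(lam, hop)
    if actp is not None and actp.T0 > 0.0:
        integrand = integrand + activation(t, lam, actp)
    p_kpa = float(np.sum(integrand / r * w))
    return p_kpa * KPA_TO_MMHG


def mean_active_tension(V: float, t: float, geom: ChamberGeometry, actp: ActivationParams) -> float:
    """Wall-volume-averaged active tension (kPa)."""
    r, lam, w = _wall_quadrature(V, geom)
    # weights w are dr; volume weighting uses r^2 dr
    vol_w = w * r**2
    return float(np.sum(activation(t, lam, actp) * vol_w) / np.sum(vol_w))


def passive_inflate(
    p_target: float, geom: ChamberGeometry, hop: HOParams, v_max: float = 1500.0
) -> float:
    """Volume (mL) at which the passive cavity pressure equals p_target (mmHg)."""
    if p_target < 0:
        raise ValueError("target pressure must be >= 0")
    v0 = geom.unloaded_cavity_volume
    if p_target == 0.0:
        return v0
    f = lambda v: cavity_pressure(v, 0.0, geom, hop) - p_target
    v_hi = v0 * 1.2
    while f(v_hi) < 0.0:
        v_hi *= 1.3
        if v_hi > v_max:
            raise ValueError(
                f"pressure {p_target} mmHg not reachable below V={v_max} mL "
                f"(achievable up to {cavity_pressure(v_max, 0.0, geom, hop):.2f} mmHg)"
            )
    v = brentq(f, v0, v_hi, xtol=1e-10, rtol=1e-12)
    return float(v)


@dataclass
class ReducedLV:
    """Bundle of chamber geometry and material/activation parameters."""

    geom: ChamberGeometry
    ho: HOParams
    act: ActivationParams

    def pressure(self, V: float, t: float) -> float:
        return cavity_pressure(V, t, self.geom, self.ho, self.act)

    def passive_pressure(self, V: float) -> float:
        return cavity_pressure(V, 0.0, self.geom, self.ho)

    def mean_tension(self, V: float, t: float) -> float:
        return mean_active_tension(V, t, self.geom, self.act)

    def edv_at(self, edp_mmhg: float) -> float:
        return passive_inflate(edp_mmhg, self.geom, self.ho)


def _fit_passive_scale(edv: float, edp: float, geom: ChamberGeometry, hop: HOParams) -> float:
    """Stiffness scale such that the passive pressure at EDV equals EDP."""
    p_unit = cavity_pressure(edv, 0.0, geom, replace(hop, stiffness_scale=1.0))
    if p_unit <= 0:
        raise ValueError("target EDV is below the unloaded cavity volume")
    # pressure is linear in the a-type constants at fixed kinematics
    return float(hop.stiffness_scale * 0.0 + edp / p_unit)


def calibrate_baseline(
    targets: dict,
    geom: ChamberGeometry,
    hop: HOParams,
    actp: ActivationParams,
    cycle_runner,
    edp_mmhg: float = 8.0,
    rel_tol: float = 0.02,
    max_outer: int = 6,
) -> tuple[HOParams, ActivationParams, dict]:
    """Match the chamber to target EDV, SV and ejection time.

    ``targets`` holds {"EDV": mL, "SV": mL, "t_ej": s}.  The passive
    stiffness scale is solved in closed form (pressure is linear in the
    a-type constants); T0 follows from a secant iteration on the stroke
    volume of a coupled cycle produced by ``cycle_runner(hop, actp)``,
    which must return ``(SV, t_ej)``; the twitch duration is updated
    proportionally to the ejection-time mismatch.

    Returns the adjusted parameter sets and a residual report.
    """
    edv, sv_t, tej_t = targets["EDV"], targets["SV"], targets["t_ej"]
    if not (0 < sv_t < edv):
        raise ValueError("need 0 < SV < EDV")
    scale = _fit_passive_scale(edv, edp_mmhg, geom, hop)
    hop = replace(hop, stiffness_scale=scale)

    sv, tej = cycle_runner(hop, actp)
    history = [(actp.T0, actp.twitch_duration, sv, tej)]
    for _ in range(max_outer):
        if abs(sv - sv_t) <= rel_tol * sv_t and abs(tej - tej_t) <= rel_tol * tej_t:
            break
        if abs(tej - tej_t) > rel_tol * tej_t and tej > 0:
            # clamp: ejection may be volume-limited rather than twitch-limited,
            # and a long twitch lets ejection creep under decaying afterloads
            ratio = min(max(tej_t / tej, 0.5), 1.6)
            actp = replace(
                actp,
                twitch_duration=min(actp.twitch_duration * ratio, 0.44),
            )
        # secant on T0 against SV, seeded by a proportional step
        T0_a, sv_a = actp.T0, sv
        actp = replace(actp, T0=actp.T0 * (sv_t / max(sv, 1e-6)) ** 0.7)
        sv, tej = cycle_runner(hop, actp)
        history.append((actp.T0, actp.twitch_duration, sv, tej))
        for _ in range(6):
            if abs(sv - sv_t) <= rel_tol * sv_t:
                break
            dsv = sv - sv_a
            if abs(dsv) < 1e-9:
                break
            T0_new = actp.T0 - (sv - sv_t) * (actp.T0 - T0_a) / dsv
            T0_new = min(max(T0_new, 0.2 * actp.T0), 5.0 * actp.T0)
            T0_a, sv_a = actp.T0, sv
            actp = replace(actp, T0=T0_new)
            sv, tej = cycle_runner(hop, actp)
            history.append((actp.T0, actp.twitch_duration, sv, tej))
    report = {
        "passive_scale": scale,
        "T0": actp.T0,
        "twitch_duration": actp.twitch_duration,
        "SV": sv,
        "t_ej": tej,
        "SV_residual": (sv - sv_t) / sv_t,
        "t_ej_residual": (tej - tej_t) / tej_t if tej_t else float("nan"),
        "evaluations": len(history),
    }
    return hop, actp, report
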