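"""Two-step Lax-Wendroff solver for the 1D large-artery network.

Mass and momentum on each tapered segment,

    A_t + Q_x = 0,
    Q_t + (Q^2/A + B)_x = S_geom + S_fric,      B = f(r0) sqrt(A0 A) / rho,

with f = (4/3) Eh/r0 from the tube law, the taper source

    S_geom = (dr0/dx / rho) [2 sqrt(pi A) f + (2 sqrt(A0 A) - A) f'],

and the boundary-layer friction S_fric = -(2 pi nu R / delta*) (Q/A).

Interior nodes advance with the Richtmyer two-step (half-point predictor,
full-step corrector).  A well-balanced correction subtracts the constant
discrete residual of the quiescent state (A = A0, Q = 0), so rest is an
exact fixed point even on tapered grids.  Boundary nodes close with
conservative ghost half-cell continuity: each boundary node's area
updates from the same corrected interface flux the interior used plus
the physical boundary flow, and the physical condition (prescribed
inflow, junction pressure continuity, or the structured-tree
convolution) closes the boundary flows by Newton iteration, so the whole
network conserves mass to round-off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .network_model import (
    ArterialNetwork,
    TubeLawParams,
    VesselSegment,
    wall_stiffness,
    wave_speed,
)
from .structured_tree import ImpedanceSpectrum, TreeParams, build_tree, root_impedance
from .units import MMHG

__all__ = [
    "SolverSettings",
    "FlowState",
    "NetworkDiscretization",
    "SASolver",
    "SimulationResult",
    "SolverError",
    "interior_step",
    "inlet_bc",
    "junction_solve",
    "terminal_bc",
    "terminal_impedances",
    "run_sa",
]

log = logging.getLogger(__name__)


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    """Time step, CFL policy and junction iteration controls."""

    dt: float = 0.9 / 8192
    t_period: float = 0.9
    cfl_limit: float = 1.0
    cfl_build: float = 0.6  # design CFL at rest when choosing dx
    junction_tolerance: float = 1.0e-12
    max_junction_iters: int = 60

    def __post_init__(self):
        if self.dt <= 0 or self.t_period <= 0:
            raise ValueError("dt and t_period must be > 0")
        if not (0 < self.cfl_limit <= 1.0):
            raise ValueError("cfl_limit in (0, 1]")
        n = self.t_period / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_period must be an integer multiple of dt")

    @property
    def steps_per_period(self) -> int:
        return int(round(self.t_period / self.dt))


@dataclass
class FlowState:
    """Per-segment (A, Q) fields at the current time.

    ``iface`` holds, after an interior step, the corrected half-step mass
    flux at each segment's first and last cell interface; the boundary
    closures consume it to keep the scheme conservative.
    """

    A: dict[int, np.ndarray]
    Q: dict[int, np.ndarray]
    t: float = 0.0
    step: int = 0
    iface: dict[int, tuple[float, float]] = field(default_factory=dict)

    def copy(self) -> "FlowState":
        return FlowState(
            A={k: v.copy() for k, v in self.A.items()},
            Q={k: v.copy() for k, v in self.Q.items()},
            t=self.t,
            step=self.step,
            iface=dict(self.iface),
        )


class _SegmentGrid:
    """Precomputed geometry arrays for one segment (nodes and half nodes)."""

    def __init__(self, seg: VesselSegment, law: TubeLawParams, settings: SolverSettings):
        c_rest = wave_speed(math.pi * seg.r_bottom**2, seg.r_bottom, law)
        dx_max = c_rest * settings.dt / settings.cfl_build
        n = max(3, int(math.ceil(seg.length / dx_max)) + 1)
        if seg.n_grid is not None:
            n = max(n, seg.n_grid)
        self.seg = seg
        self.n = n
        self.x = np.linspace(0.0, seg.length, n)
        self.dx = self.x[1] - self.x[0]
        self.law = law
        for attr, xs in (("", self.x), ("h", 0.5 * (self.x[1:] + self.x[:-1]))):
            r0 = seg.r0_at(xs)
            stiff = wall_stiffness(r0, law)
            setattr(self, "r0" + attr, r0)
            setattr(self, "A0" + attr, math.pi * r0**2)
            setattr(self, "f" + attr, (4.0 / 3.0) * stiff)
            setattr(
                self, "fp" + attr, (4.0 / 3.0) * law.k1 * law.k2 * np.exp(law.k2 * r0)
            )
            setattr(self, "dr0dx" + attr, seg.dr0dx_at(xs))
        self.c_rest = wave_speed(self.A0, self.r0, law)
        # rest-state residual of one Lax-Wendroff step (well-balanced offset);
        # the rest half-step fluxes also offset the boundary-cell updates
        self._rest_dA = np.zeros(n)
        self._rest_dQ = np.zeros(n)
        self._rest_Qh = np.zeros(n - 1)
        dA, dQ, Qh = self._lw_increment(self.A0.copy(), np.zeros(n), settings.dt)
        self._rest_dA, self._rest_dQ, self._rest_Qh = dA, dQ, Qh

    # tube-law helpers at a single boundary node -----------------------

    def c_of(self, A, end: int):
        i = 0 if end == 0 else self.n - 1
        return float(self.c_rest[i]) * (float(self.A0[i]) / A) ** 0.25

    def p_of(self, A, end: int):
        i = 0 if end == 0 else self.n - 1
        return self.law.P0 + float(self.f[i]) * (1.0 - math.sqrt(float(self.A0[i]) / A))

    def dpdA_of(self, A, end: int):
        i = 0 if end == 0 else self.n - 1
        return float(self.f[i]) * math.sqrt(float(self.A0[i])) / (2.0 * A**1.5)

    # Lax-Wendroff interior increment ----------------------------------

    def _flux_source(self, A, Q, r0, A0, f, fp, dr0dx):
        rho = self.law.rho
        F2 = Q * Q / A + f * np.sqrt(A0 * A) / rho
        R = np.sqrt(A / math.pi)
        fric = -(2.0 * math.pi * self.law.nu * R / self.law.delta_star) * (Q / A)
        geom = (dr0dx / rho) * (2.0 * np.sqrt(math.pi * A) * f + (2.0 * np.sqrt(A0 * A) - A) * fp)
        return F2, fric + geom

    def _lw_increment(self, A, Q, dt):
        """Raw interior increments (before the well-balanced offset)."""
        dx = self.dx
        F2, S = self._flux_source(A, Q, self.r0, self.A0, self.f, self.fp, self.dr0dx)
        Ah = 0.5 * (A[1:] + A[:-1]) - (dt / (2 * dx)) * (Q[1:] - Q[:-1])
        Qh = (
            0.5 * (Q[1:] + Q[:-1])
            - (dt / (2 * dx)) * (F2[1:] - F2[:-1])
            + (dt / 4.0) * (S[1:] + S[:-1])
        )
        if np.any(Ah <= 0.0):
            raise SolverError(f"negative area in segment {self.seg.id} (half step)")
        F2h, Sh = self._flux_source(Ah, Qh, self.r0h, self.A0h, self.fh, self.fph, self.dr0dxh)
        dA = np.zeros_like(A)
        dQ = np.zeros_like(Q)
        dA[1:-1] = -(dt / dx) * (Qh[1:] - Qh[:-1])
        dQ[1:-1] = -(dt / dx) * (F2h[1:] - F2h[:-1]) + (dt / 2.0) * (Sh[1:] + Sh[:-1])
        return dA, dQ, Qh

    def interior_increment(self, A, Q, dt):
        """Well-balanced increments plus the corrected end interface fluxes.

        Returns (dA, dQ, qh_left, qh_right): the half-step mass fluxes at
        the first and last cell interfaces (rest-flux subtracted), which
        the boundary half-cell continuity updates re-use so the whole
        segment is conservative to round-off.
        """
        dA, dQ, Qh = self._lw_increment(A, Q, dt)
        qh = Qh - self._rest_Qh
        return dA - self._rest_dA, dQ - self._rest_dQ, float(qh[0]), float(qh[-1])

    def cfl(self, A, Q, dt) -> float:
        c = self.c_rest * (self.A0 / A) ** 0.25
        return float(np.max(np.abs(Q / A) + c)) * dt / self.dx


class NetworkDiscretization:
    """Grids plus topology lists (bifurcations, serial junctions, terminals)."""

    def __init__(self, net: ArterialNetwork, settings: SolverSettings):
        self.net = net
        self.settings = settings
        self.grids: dict[int, _SegmentGrid] = {
            sid: _SegmentGrid(seg, net.tube_law, settings)
            for sid, seg in net.segments.items()
        }
        self.bifurcations: list[tuple[int, int, int]] = []
        self.serials: list[tuple[int, int]] = []
        self.terminals: list[int] = []
        for sid, seg in net.segments.items():
            if len(seg.daughters) == 2:
                self.bifurcations.append((sid, *seg.daughters))
            elif len(seg.daughters) == 1:
                self.serials.append((sid, seg.daughters[0]))
            else:
                self.terminals.append(sid)

    def rest_state(self) -> FlowState:
        return FlowState(
            A={sid: g.A0.copy() for sid, g in self.grids.items()},
            Q={sid: np.zeros(g.n) for sid, g in self.grids.items()},
        )


def interior_step(state: FlowState, disc: NetworkDiscretization) -> FlowState:
    """Advance interior nodes one dt; boundary nodes are left untouched."""
    s = disc.settings
    new = state.copy()
    for sid, g in disc.grids.items():
        A, Q = state.A[sid], state.Q[sid]
        cfl = g.cfl(A, Q, s.dt)
        if cfl > s.cfl_limit:
            raise SolverError(
                f"CFL violation in segment {sid} ({g.seg.name}): {cfl:.3f}"
            )
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(Q))):
            raise SolverError(f"non-finite state in segment {sid}")
        dA, dQ, qh_l, qh_r = g.interior_increment(A, Q, s.dt)
        new.A[sid] = A + dA
        new.Q[sid] = Q + dQ
        new.iface[sid] = (qh_l, qh_r)
    new.t = state.t + s.dt
    new.step = state.step + 1
    return new


# ---------------------------------------------------------------------------
# boundary closures (conservative ghost half-cell continuity)
#
# The boundary node at each segment end owns a half cell of width dx/2.
# Its area updates from the same corrected interface flux the interior
# used plus the physical boundary flow averaged over the step,
#
#   A_0^{n+1} = A_0^n + (2 dt/dx) ((Q_0^n + Q_0^{n+1})/2 - qh_left),
#   A_m^{n+1} = A_m^n + (2 dt/dx) (qh_right - (Q_m^n + Q_m^{n+1})/2),
#
# so every control volume is in discrete flux form and the network
# conserves mass to round-off.  The physical condition (prescribed
# inflow, pressure continuity, or the impedance convolution) then closes
# the boundary flows by Newton iteration on Q.
# ---------------------------------------------------------------------------


def _inlet_area(g: _SegmentGrid, q: float, A_old: float, Q_old: float, qh_left: float, dt: float) -> float:
    A = A_old + (2.0 * dt / g.dx) * (0.5 * (Q_old + q) - qh_left)
    if A <= 0.0:
        raise SolverError(f"inlet area collapse on segment {g.seg.id}")
    return A


def _solve_terminal(
    g: _SegmentGrid,
    A_old: float,
    Q_old: float,
    qh_right: float,
    z0dt: float,
    H: float,
    dt: float,
):
    """Distal (A, Q) from the convolution relation P - P0 = H + z(0) dt Q
    combined with the boundary half-cell continuity update."""
    P0 = g.law.P0
    k = 2.0 * dt / g.dx

    def area(q):
        return A_old + k * (qh_right - 0.5 * (Q_old + q))

    q = Q_old
    for _ in range(80):
        A = area(q)
        if A <= 0.0:
            raise SolverError(f"terminal area collapse on segment {g.seg.id}")
        F = (g.p_of(A, 1) - P0) - H - z0dt * q
        dF = g.dpdA_of(A, 1) * (-0.5 * k) - z0dt
        dq = -F / dF
        q += dq
        if abs(dq) < 1e-12 * (abs(q) + 1.0):
            return area(q), q
    raise SolverError(f"terminal Newton failed on segment {g.seg.id}")


def _junction_newton(parent, daughters, old_p, old_ds, qh_p, qh_ds, dt, tol, max_iters):
    """Newton solve of flow conservation + pressure continuity.

    Unknowns are the boundary flows (parent distal, each daughter
    proximal); areas follow from the half-cell continuity updates.
    Handles 1 or 2 daughters.
    """
    nd = len(daughters)
    A_old_p, Q_old_p = old_p
    kp = 2.0 * dt / parent.dx
    kd = [2.0 * dt / g.dx for g in daughters]
    p_scale = parent.law.P0 + float(parent.f[-1])
    q = np.array([Q_old_p] + [od[1] for od in old_ds], dtype=float)

    def areas(q):
        Ap = A_old_p + kp * (qh_p - 0.5 * (Q_old_p + q[0]))
        Ad = [
            old_ds[i][0] + kd[i] * (0.5 * (old_ds[i][1] + q[1 + i]) - qh_ds[i])
            for i in range(nd)
        ]
        return Ap, Ad

    converged = False
    for _ in range(max_iters):
        Ap, Ad = areas(q)
        if Ap <= 0.0 or any(a <= 0.0 for a in Ad):
            raise SolverError(f"junction area collapse at segment {parent.seg.id}")
        G = np.empty(1 + nd)
        G[0] = q[0] - q[1:].sum()
        Pp = parent.p_of(Ap, 1)
        for i, g in enumerate(daughters):
            G[1 + i] = Pp - g.p_of(Ad[i], 0)
        flux_scale = abs(q[0]) + parent.c_of(Ap, 1) * Ap
        if abs(G[0]) <= max(tol * flux_scale, 1e-14) and np.max(
            np.abs(G[1:])
        ) <= max(tol * abs(p_scale), 1e-10):
            converged = True
            break
        J = np.zeros((1 + nd, 1 + nd))
        J[0, 0] = 1.0
        J[0, 1:] = -1.0
        dPp_dq = parent.dpdA_of(Ap, 1) * (-0.5 * kp)
        for i, g in enumerate(daughters):
            J[1 + i, 0] = dPp_dq
            J[1 + i, 1 + i] = -g.dpdA_of(Ad[i], 0) * (0.5 * kd[i])
        try:
            dq = np.linalg.solve(J, -G)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular junction Jacobian at segment {parent.seg.id}") from exc
        q = q + dq
    if not converged:
        raise SolverError(
            f"junction at segment {parent.seg.id} did not converge: residuals {G}"
        )
    # exact conservation by construction of the converged linear relation
    q[0] = q[1:].sum()
    Ap, Ad = areas(q)
    return [Ap] + Ad, list(q)


# public single-boundary operations -----------------------------------------


def inlet_bc(
    new: FlowState,
    old: FlowState,
    disc: NetworkDiscretization,
    q_in: float,
) -> FlowState:
    """Apply the prescribed-inflow closure at the root proximal node.

    Sets Q = q_in and updates the area from the boundary half-cell
    continuity; interior nodes of ``new`` must already be advanced (its
    ``iface`` fluxes are consumed here).
    """
    root = disc.net.root_id
    g = disc.grids[root]
    A = _inlet_area(
        g, q_in, old.A[root][0], old.Q[root][0], new.iface[root][0], disc.settings.dt
    )
    new.A[root][0] = A
    new.Q[root][0] = q_in
    return new


def junction_solve(
    new: FlowState,
    old: FlowState,
    disc: NetworkDiscretization,
    parent_id: int,
) -> dict:
    """Couple a parent's distal node to its daughters' proximal nodes.

    Flow conservation and static pressure continuity solved together with
    the adjoining characteristics by Newton iteration; handles both
    bifurcations and serial (single-daughter) connections.  Returns the
    converged residual diagnostics.
    """
    s = disc.settings
    dids = list(disc.net.segments[parent_id].daughters)
    if not dids:
        raise ValueError(f"segment {parent_id} is terminal; no junction to solve")
    gp = disc.grids[parent_id]
    gds = [disc.grids[d] for d in dids]
    A, Qs = _junction_newton(
        gp,
        gds,
        (old.A[parent_id][-1], old.Q[parent_id][-1]),
        [(old.A[d][0], old.Q[d][0]) for d in dids],
        new.iface[parent_id][1],
        [new.iface[d][0] for d in dids],
        s.dt,
        s.junction_tolerance,
        s.max_junction_iters,
    )
    new.A[parent_id][-1] = A[0]
    new.Q[parent_id][-1] = Qs[0]
    for i, d in enumerate(dids):
        new.A[d][0] = A[1 + i]
        new.Q[d][0] = Qs[1 + i]
    p_par = gp.p_of(A[0], 1)
    return {
        "flow_residual": Qs[0] - sum(Qs[1:]),
        "pressure_residuals": [p_par - g.p_of(A[1 + i], 0) for i, g in enumerate(gds)],
    }


def terminal_bc(
    new: FlowState,
    old: FlowState,
    disc: NetworkDiscretization,
    sid: int,
    z: np.ndarray,
    history: np.ndarray,
) -> FlowState:
    """Apply the structured-tree convolution closure at a terminal node.

    ``z`` is the bed's periodic impulse response sampled at the solver
    step; ``history`` holds the terminal flow over the previous period in
    a ring buffer indexed by step modulo N.
    """
    s = disc.settings
    N = s.steps_per_period
    if len(z) != N or len(history) != N:
        raise ValueError("impulse response and history must span one period")
    g = disc.grids[sid]
    n1 = new.step
    idx = (n1 - np.arange(1, N)) % N
    H = s.dt * float(np.dot(z[1:], history[idx]))
    A_T, Q_T = _solve_terminal(
        g, old.A[sid][-1], old.Q[sid][-1], new.iface[sid][1], z[0] * s.dt, H, s.dt
    )
    new.A[sid][-1] = A_T
    new.Q[sid][-1] = Q_T
    return new


# ---------------------------------------------------------------------------
# orchestrating solver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Probed time series of a run, in clinical units."""

    t: np.ndarray  # s
    probes: dict  # name -> {"P": mmHg, "Q": mL/s, "A": cm^2}
    inflow: np.ndarray  # mL/s at the root proximal node
    meta: dict = field(default_factory=dict)

    def period_slice(self, i: int, steps_per_period: int) -> slice:
        return slice(i * steps_per_period, (i + 1) * steps_per_period)


def terminal_impedances(
    net: ArterialNetwork,
    tree: TreeParams,
    settings: SolverSettings,
    wall_law: TubeLawParams | None = None,
) -> dict[int, ImpedanceSpectrum]:
    """Structured-tree impedance spectra for every terminal segment.

    Beds sharing a root radius share the computed spectrum.
    """
    wall = wall_law if wall_law is not None else net.tube_law
    N = settings.steps_per_period
    cache: dict[float, ImpedanceSpectrum] = {}
    out = {}
    for seg in net.terminal_segments():
        r = seg.bed_root_radius
        if r is None:
            raise ValueError(f"terminal segment {seg.id} has no bed root radius")
        key = round(r, 10)
        if key not in cache:
            cache[key] = root_impedance(build_tree(r, tree), settings.t_period, N, wall)
        out[seg.id] = cache[key]
    return out


class SASolver:
    """Time stepper for the systemic-artery network.

    Splits each step so a coupled chamber model can iterate on the inlet
    flow: ``begin_step`` advances interiors, junctions and terminals;
    ``inlet_pressure_for`` evaluates trial inlet states; ``commit_step``
    fixes the inlet flow and finalizes the step.
    """

    def __init__(
        self,
        net: ArterialNetwork,
        settings: SolverSettings,
        beds: dict[int, ImpedanceSpectrum],
        probes: list | None = None,
        record: bool = True,
    ):
        self.net = net
        self.settings = settings
        self.disc = NetworkDiscretization(net, settings)
        missing = [sid for sid in self.disc.terminals if sid not in beds]
        if missing:
            raise ValueError(f"missing impedance for terminal segments {missing}")
        N = settings.steps_per_period
        for sid in self.disc.terminals:
            if beds[sid].N != N:
                raise ValueError(
                    f"impedance for segment {sid} tabulated at N={beds[sid].N}, "
                    f"solver uses {N}"
                )
        self.beds = beds
        self.state = self.disc.rest_state()
        self.hist = {sid: np.zeros(N) for sid in self.disc.terminals}
        self._pending: FlowState | None = None
        self.max_cfl = 0.0
        self.junction_iters: list[int] = []
        self.record = record
        if probes is None:
            probes = [(sid, 0.5, f"{net.segments[sid].name}_mid") for sid in sorted(net.segments)]
        self.probes = []
        for sid, frac, name in probes:
            g = self.disc.grids[sid]
            pos = frac * g.seg.length
            i = min(int(pos / g.dx), g.n - 2)
            w = (pos - g.x[i]) / g.dx
            self.probes.append((sid, i, w, name))
        self._records: dict[str, dict[str, list]] = {
            name: {"P": [], "Q": [], "A": []} for *_ , name in self.probes
        }
        self._t_rec: list[float] = []
        self._q_in_rec: list[float] = []

    # -- stepping ------------------------------------------------------

    def begin_step(self) -> None:
        if self._pending is not None:
            raise SolverError("begin_step called twice without commit")
        old = self.state
        s = self.settings
        new = interior_step(old, self.disc)
        for sid, g in self.disc.grids.items():
            self.max_cfl = max(self.max_cfl, g.cfl(old.A[sid], old.Q[sid], s.dt))
        # junctions (bifurcations and serial connections)
        for pid, *dids in self.disc.bifurcations + [list(t) for t in self.disc.serials]:
            gp = self.disc.grids[pid]
            gds = [self.disc.grids[d] for d in dids]
            A, Qs = _junction_newton(
                gp,
                gds,
                (old.A[pid][-1], old.Q[pid][-1]),
                [(old.A[d][0], old.Q[d][0]) for d in dids],
                new.iface[pid][1],
                [new.iface[d][0] for d in dids],
                s.dt,
                s.junction_tolerance,
                s.max_junction_iters,
            )
            new.A[pid][-1] = A[0]
            new.Q[pid][-1] = Qs[0]
            for i, d in enumerate(dids):
                new.A[d][0] = A[1 + i]
                new.Q[d][0] = Qs[1 + i]
        # terminals (periodic convolution of the bed impulse response)
        N = s.steps_per_period
        n1 = new.step
        for sid in self.disc.terminals:
            g = self.disc.grids[sid]
            z = self.beds[sid].z
            idx = (n1 - np.arange(1, N)) % N
            H = s.dt * float(np.dot(z[1:], self.hist[sid][idx]))
            A_T, Q_T = _solve_terminal(
                g, old.A[sid][-1], old.Q[sid][-1], new.iface[sid][1], z[0] * s.dt, H, s.dt
            )
            new.A[sid][-1] = A_T
            new.Q[sid][-1] = Q_T
        self._pending = new

    def _inlet_area_for(self, q: float) -> float:
        root = self.net.root_id
        g = self.disc.grids[root]
        return _inlet_area(
            g,
            q,
            self.state.A[root][0],
            self.state.Q[root][0],
            self._pending.iface[root][0],
            self.settings.dt,
        )

    def inlet_pressure_for(self, q: float) -> float:
        """Trial inlet pressure (CGS) for a candidate inflow at t + dt."""
        if self._pending is None:
            raise SolverError("no pending step")
        g = self.disc.grids[self.net.root_id]
        return g.p_of(self._inlet_area_for(q), 0)

    def commit_step(self, q_in: float) -> None:
        if self._pending is None:
            raise SolverError("no pending step")
        new = self._pending
        root = self.net.root_id
        A = self._inlet_area_for(q_in)
        new.A[root][0] = A
        new.Q[root][0] = q_in
        N = self.settings.steps_per_period
        for sid in self.disc.terminals:
            self.hist[sid][new.step % N] = new.Q[sid][-1]
        self.state = new
        self._pending = None
        if self.record:
            self._record_now(q_in)

    def step(self, q_in: float) -> None:
        self.begin_step()
        self.commit_step(q_in)

    # -- probing -------------------------------------------------------

    def _record_now(self, q_in: float) -> None:
        st = self.state
        for sid, i, w, name in self.probes:
            g = self.disc.grids[sid]
            A = (1 - w) * st.A[sid][i] + w * st.A[sid][i + 1]
            Q = (1 - w) * st.Q[sid][i] + w * st.Q[sid][i + 1]
            r0 = (1 - w) * g.r0[i] + w * g.r0[i + 1]
            f = (1 - w) * g.f[i] + w * g.f[i + 1]
            P = g.law.P0 + f * (1.0 - math.sqrt(math.pi * r0**2 / A))
            rec = self._records[name]
            rec["P"].append(P / MMHG)
            rec["Q"].append(Q)
            rec["A"].append(A)
        self._t_rec.append(st.t)
        self._q_in_rec.append(q_in)

    def result(self) -> SimulationResult:
        probes = {
            name: {k: np.asarray(v) for k, v in rec.items()}
            for name, rec in self._records.items()
        }
        meta = {
            "max_cfl": self.max_cfl,
            "dt": self.settings.dt,
            "t_period": self.settings.t_period,
            "steps_per_period": self.settings.steps_per_period,
            "n_grid": {sid: g.n for sid, g in self.disc.grids.items()},
        }
        return SimulationResult(
            t=np.asarray(self._t_rec),
            probes=probes,
            inflow=np.asarray(self._q_in_rec),
            meta=meta,
        )

    def terminal_outflow_rates(self) -> dict[int, float]:
        return {sid: float(self.state.Q[sid][-1]) for sid in self.disc.terminals}


def run_sa(
    net: ArterialNetwork,
    inflow,
    beds: dict[int, ImpedanceSpectrum],
    periods: int,
    probes: list | None = None,
    settings: SolverSettings | None = None,
    solver: SASolver | None = None,
    record_terminals: bool = False,
) -> tuple[SimulationResult, SASolver]:
    """Run the SA model alone with a prescribed inflow waveform.

    ``inflow`` is a callable q(t) in mL/s.  Returns the probed result and
    the solver (whose state can seed a subsequent coupled run).
    """
    if periods < 1:
        raise ValueError("periods >= 1")
    settings = settings or SolverSettings()
    if solver is None:
        if record_terminals and probes is None:
            probes = [
                (sid, 0.5, f"{net.segments[sid].name}_mid") for sid in sorted(net.segments)
            ] + [
                (sid, 1.0, f"{net.segments[sid].name}_outlet")
                for sid in sorted(net.segments)
                if net.segments[sid].is_terminal
            ]
        solver = SASolver(net, settings, beds, probes=probes)
    n = settings.steps_per_period * periods
    for _ in range(n):
        solver.step(float(inflow(solver.state.t + settings.dt)))
    return solver.result(), solver
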