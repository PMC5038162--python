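"""Large-artery network geometry and the elastic tube law.

The systemic arteries are represented as a rooted tree of tapered elastic
vessels. The wall model is the exponential stiffness law

    Eh/r0 = k1 * exp(k2 * r0) + k3,

and the tube law relating transmural pressure to cross-sectional area is

    P - P0 = (4/3) (Eh/r0) (1 - sqrt(A0/A)),      A0 = pi r0^2,

so that stiffness decreases with unstressed radius r0 (k1 > 0, k2 < 0) and
the pressure-area relation saturates at P0 + (4/3) Eh/r0.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .units import MMHG

__all__ = [
    "TubeLawParams",
    "VesselSegment",
    "ArterialNetwork",
    "wall_stiffness",
    "pressure_from_area",
    "area_from_pressure",
    "wave_speed",
    "load_network_csv",
    "save_network_csv",
    "default24",
]

#: cardiac period (s) used throughout unless overridden
DEFAULT_PERIOD = 0.9


def _default_delta_star(nu: float, t_period: float = DEFAULT_PERIOD) -> float:
    # Womersley oscillatory boundary-layer estimate sqrt(nu T / 2 pi)
    return math.sqrt(nu * t_period / (2.0 * math.pi))


@dataclass(frozen=True)
class TubeLawParams:
    """Wall-law and fluid constants, CGS units.

    k1 : g s^-2 cm^-1   exponential stiffness amplitude
    k2 : cm^-1          exponential rate (negative)
    k3 : g s^-2 cm^-1   stiffness offset
    P0 : dyn cm^-2      external reference pressure (CGS internally)
    rho : g cm^-3       blood density
    nu : cm^2 s^-1      kinematic viscosity
    delta_star : cm     viscous boundary-layer width (<< vessel radius)
    """

    k1: float = 2.0e7
    k2: float = -22.53
    k3: float = 8.65e5
    P0: float = 0.0
    rho: float = 1.055
    nu: float = 0.049 / 1.055
    delta_star: float = field(default=-1.0)

    def __post_init__(self):
        if self.delta_star <= 0.0:
            object.__setattr__(
                self, "delta_star", _default_delta_star(self.nu)
            )
        if self.k1 < 0:
            raise ValueError("k1 must be >= 0")
        if self.k3 <= 0:
            raise ValueError("k3 must be > 0")
        if self.rho <= 0 or self.nu <= 0:
            raise ValueError("rho and nu must be > 0")

    @property
    def mu(self) -> float:
        """Dynamic viscosity (g cm^-1 s^-1)."""
        return self.nu * self.rho

    @classmethod
    def with_p0_mmhg(cls, p0_mmhg: float, **kw) -> "TubeLawParams":
        return cls(P0=p0_mmhg * MMHG, **kw)


def wall_stiffness(r0, p: TubeLawParams):
    """Eh/r0 (g s^-2 cm^-1) for unstressed radius r0 (cm).

    Strictly decreasing in r0 when k1 > 0 and k2 < 0.
    """
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ValueError("unstressed radius must be positive")
    out = p.k1 * np.exp(p.k2 * r0) + p.k3
    return float(out) if out.ndim == 0 else out


def _f_elastic(r0, p: TubeLawParams):
    """(4/3) Eh/r0, the tube-law prefactor."""
    return (4.0 / 3.0) * wall_stiffness(r0, p)


def pressure_from_area(A, r0, p: TubeLawParams):
    """Transmural pressure (dyn cm^-2) at area A (cm^2)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be positive")
    A0 = math.pi * np.asarray(r0, dtype=float) ** 2
    out = p.P0 + _f_elastic(r0, p) * (1.0 - np.sqrt(A0 / A))
    return float(out) if out.ndim == 0 else out


def area_from_pressure(P, r0, p: TubeLawParams):
    """Analytic inverse of :func:`pressure_from_area`.

    Valid below the tube-law asymptote P0 + (4/3) Eh/r0.
    """
    P = np.asarray(P, dtype=float)
    f = _f_elastic(r0, p)
    if np.any(P - p.P0 >= f):
        p_asym = (p.P0 + np.min(np.broadcast_to(f, P.shape))) / MMHG
        raise ValueError(
            "pressure at or above the tube-law asymptote "
            f"({p_asym:.1f} mmHg); no finite area exists"
        )
    A0 = math.pi * np.asarray(r0, dtype=float) ** 2
    out = A0 / (1.0 - (P - p.P0) / f) ** 2
    return float(out) if out.ndim == 0 else out


def wave_speed(A, r0, p: TubeLawParams):
    """Local pulse-wave speed c = sqrt((A/rho) dP/dA) (cm s^-1).

    For this tube law c^2 = (2/(3 rho)) (Eh/r0) sqrt(A0/A), decreasing
    with distension.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be positive")
    A0 = math.pi * np.asarray(r0, dtype=float) ** 2
    c2 = (2.0 / (3.0 * p.rho)) * wall_stiffness(r0, p) * np.sqrt(A0 / A)
    out = np.sqrt(c2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# network topology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselSegment:
    """One tapered large-artery segment.

    ``daughters`` holds 0 (terminal), 1 (serial continuation) or 2
    (bifurcation) segment ids. Terminal segments carry the root radius of
    their structured-tree vascular bed.
    """

    id: int
    name: str
    length: float
    r_top: float
    r_bottom: float
    daughters: tuple[int, ...] = ()
    bed_root_radius: float | None = None
    n_grid: int | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: length must be > 0")
        if not (0 < self.r_bottom <= self.r_top):
            raise ValueError(
                f"segment {self.id}: need 0 < r_bottom <= r_top"
            )
        if len(self.daughters) not in (0, 1, 2):
            raise ValueError(f"segment {self.id}: 0, 1 or 2 daughters")
        terminal = len(self.daughters) == 0
        if terminal and self.bed_root_radius is None:
            raise ValueError(
                f"segment {self.id}: terminal segment needs bed_root_radius"
            )
        if not terminal and self.bed_root_radius is not None:
            raise ValueError(
                f"segment {self.id}: only terminal segments carry a bed"
            )
        if self.n_grid is not None and self.n_grid < 3:
            raise ValueError(f"segment {self.id}: n_grid >= 3")

    @property
    def is_terminal(self) -> bool:
        return len(self.daughters) == 0

    def r0_at(self, x) -> np.ndarray:
        """Unstressed radius at axial position x in [0, length].

        Exponential taper r0(x) = r_top (r_bottom/r_top)^(x/L); smooth in
        Eh/r0 and monotone from r_top to r_bottom.
        """
        x = np.asarray(x, dtype=float)
        return self.r_top * (self.r_bottom / self.r_top) ** (x / self.length)

    def dr0dx_at(self, x) -> np.ndarray:
        return self.r0_at(x) * math.log(self.r_bottom / self.r_top) / self.length


class ArterialNetwork:
    """Rooted tree of :class:`VesselSegment` with a shared tube law."""

    def __init__(
        self,
        segments: list[VesselSegment],
        root_id: int,
        tube_law: TubeLawParams | None = None,
    ):
        self.segments: dict[int, VesselSegment] = {s.id: s for s in segments}
        if len(self.segments) != len(segments):
            raise ValueError("duplicate segment ids")
        self.root_id = root_id
        self.tube_law = tube_law or TubeLawParams()
        self.parent: dict[int, int] = {}
        for s in segments:
            for d in s.daughters:
                if d not in self.segments:
                    raise ValueError(f"segment {s.id}: unknown daughter {d}")
                if d in self.parent:
                    raise ValueError(f"segment {d} has two parents")
                self.parent[d] = s.id
        if root_id not in self.segments:
            raise ValueError("unknown root id")
        if root_id in self.parent:
            raise ValueError("root segment must have no parent")
        # connectivity: every segment reachable from the root
        seen: set[int] = set()
        stack = [root_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ValueError("cycle in network topology")
            seen.add(sid)
            stack.extend(self.segments[sid].daughters)
        if seen != set(self.segments):
            raise ValueError("network is not connected to the root")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def root(self) -> VesselSegment:
        return self.segments[self.root_id]

    def terminal_segments(self) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.is_terminal]

    def with_tube_law(self, tube_law: TubeLawParams) -> "ArterialNetwork":
        return ArterialNetwork(
            list(self.segments.values()), self.root_id, tube_law
        )

    def segment_by_name(self, name: str) -> VesselSegment:
        for s in self.segments.values():
            if s.name == name:
                return s
        raise KeyError(name)


_CSV_FIELDS = [
    "id",
    "name",
    "length_cm",
    "r_top_cm",
    "r_bottom_cm",
    "daughter_1",
    "daughter_2",
    "bed_root_radius_cm",
]


def load_network_csv(path, tube_law: TubeLawParams | None = None) -> ArterialNetwork:
    """Read a network definition CSV (see ``data/network24.csv``)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            daughters = tuple(
                int(row[k])
                for k in ("daughter_1", "daughter_2")
                if row.get(k, "").strip()
            )
            bed = row.get("bed_root_radius_cm", "").strip()
            rows.append(
                VesselSegment(
                    id=int(row["id"]),
                    name=row["name"],
                    length=float(row["length_cm"]),
                    r_top=float(row["r_top_cm"]),
                    r_bottom=float(row["r_bottom_cm"]),
                    daughters=daughters,
                    bed_root_radius=float(bed) if bed else None,
                )
            )
    root_candidates = set(r.id for r in rows) - {
        d for r in rows for d in r.daughters
    }
    if len(root_candidates) != 1:
        raise ValueError(f"expected one root, found {sorted(root_candidates)}")
    return ArterialNetwork(rows, root_candidates.pop(), tube_law)


def save_network_csv(net: ArterialNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for s in sorted(net.segments.values(), key=lambda s: s.id):
            w.writerow(
                {
                    "id": s.id,
                    "name": s.name,
                    "length_cm": s.length,
                    "r_top_cm": s.r_top,
                    "r_bottom_cm": s.r_bottom,
                    "daughter_1": s.daughters[0] if len(s.daughters) > 0 else "",
                    "daughter_2": s.daughters[1] if len(s.daughters) > 1 else "",
                    "bed_root_radius_cm": (
                        s.bed_root_radius if s.bed_root_radius is not None else ""
                    ),
                }
            )


def default24(tube_law: TubeLawParams | None = None) -> ArterialNetwork:
    """The default 24-segment large-artery tree.

    Geometry follows the standard structured-tree systemic-artery table
    (aorta in serial pieces, head/arm/visceral/leg branches); each of the
    11 terminal segments feeds a structured-tree vascular bed rooted at its
    distal radius.
    """
    ref = importlib.resources.files("lvsa") / "data" / "network24.csv"
    with importlib.resources.as_file(ref) as path:
        return load_network_csv(Path(path), tube_law)
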