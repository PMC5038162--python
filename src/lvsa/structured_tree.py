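"""Structured-tree vascular beds and their root input impedance.

Each terminal large artery feeds an asymmetric, self-similar binary tree of
small arteries: a parent of radius r bifurcates into daughters of radii
``alpha * r`` and ``beta * r`` until the radius falls below ``r_min``.  The
scaling pair (alpha, beta) follows from the radius exponent ``xi`` in

    r_p^xi = r_d1^xi + r_d2^xi

together with the (squared) daughter-radius ratio ``gamma = (r_d1/r_d2)^2``.
Lowering ``xi`` at fixed ``gamma`` prunes the tree (vascular rarefaction).

The root input impedance of a bed is assembled from the linearized
(Womersley) oscillatory flow solution per vessel, combined recursively from
the leaves (terminal impedance zero by default) to the root.  Because the
radius of a tree node depends only on how many alpha- and beta-steps lead
to it, the recursion runs on the (j, k) scaling lattice with path-count
multiplicities, which keeps even multi-million-vessel beds cheap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import jve

from .network_model import ArterialNetwork, TubeLawParams, wall_stiffness

__all__ = [
    "TreeParams",
    "StructuredTreeBed",
    "ImpedanceSpectrum",
    "alpha_beta",
    "area_ratio",
    "build_tree",
    "count_network_vessels",
    "root_impedance",
]


@dataclass(frozen=True)
class TreeParams:
    """Structured-tree scaling parameters.

    xi        : radius exponent (2.33-3; warn outside)
    gamma     : daughter-radius ratio squared, (r_d1/r_d2)^2 with r_d1 the
                larger daughter, so gamma >= 1 internally. Values < 1 are
                accepted as the literature's asymmetry ratio and normalized
                by reciprocal.
    r_min_um  : termination radius in micrometres
    lr_ratio  : vessel length / radius
    z_terminal: impedance closing the leaves (CGS), 0 by default
    """

    xi: float = 2.76
    gamma: float = 1.0 / 0.41
    r_min_um: float = 100.0
    lr_ratio: float = 50.0
    z_terminal: float = 0.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.gamma < 1.0:
            object.__setattr__(self, "gamma", 1.0 / self.gamma)
        if not (2.33 <= self.xi <= 3.0):
            warnings.warn(
                f"radius exponent xi={self.xi} outside the usual 2.33-3 range",
                stacklevel=2,
            )
        if self.r_min_um <= 0:
            raise ValueError("r_min must be > 0")
        if self.lr_ratio <= 0:
            raise ValueError("lr_ratio must be > 0")

    @property
    def r_min_cm(self) -> float:
        return self.r_min_um * 1.0e-4


def alpha_beta(xi: float, gamma: float) -> tuple[float, float]:
    """Daughter scaling factors (alpha, beta), alpha^xi + beta^xi = 1.

    With gamma = (r_d1/r_d2)^2 >= 1:
        alpha = (1 + gamma^(-xi/2))^(-1/xi),   beta = alpha / sqrt(gamma).
    """
    if xi <= 0 or gamma <= 0:
        raise ValueError("xi and gamma must be > 0")
    if gamma < 1.0:
        gamma = 1.0 / gamma
    alpha = (1.0 + gamma ** (-xi / 2.0)) ** (-1.0 / xi)
    beta = alpha / math.sqrt(gamma)
    if alpha >= 1.0:
        raise ValueError("parameters give alpha >= 1: tree would not terminate")
    return alpha, beta


def area_ratio(xi: float, gamma: float) -> float:
    """Total daughter area over parent area, (1+gamma)/(1+gamma^(xi/2))^(2/xi)."""
    if gamma < 1.0:
        gamma = 1.0 / gamma
    return (1.0 + gamma) / (1.0 + gamma ** (xi / 2.0)) ** (2.0 / xi)


class StructuredTreeBed:
    """One generated vascular bed.

    The tree is stored implicitly on the (j, k) scaling lattice: a lattice
    node represents every tree vessel whose radius is
    ``root_radius * alpha^j * beta^k``; ``mult[(j, k)]`` counts them.
    """

    def __init__(self, root_radius: float, params: TreeParams):
        if root_radius <= 0:
            raise ValueError("root radius must be > 0")
        self.root_radius = root_radius
        self.params = params
        self.alpha, self.beta = alpha_beta(params.xi, params.gamma)
        r_min = params.r_min_cm
        # lattice of reachable nodes: (0,0) always; a node exists if one of
        # its lattice parents exists and is internal (radius >= r_min)
        radius: dict[tuple[int, int], float] = {(0, 0): root_radius}
        mult: dict[tuple[int, int], int] = {(0, 0): 1}
        frontier = [(0, 0)]
        while frontier:
            nxt: dict[tuple[int, int], int] = {}
            for jk in frontier:
                if radius[jk] < r_min:
                    continue  # leaf: does not spawn daughters
                j, k = jk
                m = mult[jk]
                for child, scale in (((j + 1, k), self.alpha), ((j, k + 1), self.beta)):
                    nxt[child] = nxt.get(child, 0) + m
                    radius.setdefault(child, radius[jk] * scale)
            for child, m in nxt.items():
                mult[child] = mult.get(child, 0) + m
            frontier = list(nxt)
        self._radius = radius
        self._mult = mult
        self.vessel_count = sum(mult.values())
        self.leaf_count = sum(
            m for jk, m in mult.items() if radius[jk] < r_min
        )
        if root_radius < r_min:
            # degenerate single-vessel bed
            assert self.vessel_count == 1 and self.leaf_count == 1

    def lattice(self) -> list[tuple[tuple[int, int], float, int]]:
        """(node, radius, multiplicity) triples, deepest first."""
        return sorted(
            ((jk, self._radius[jk], self._mult[jk]) for jk in self._mult),
            key=lambda t: -(t[0][0] + t[0][1]),
        )

    def is_leaf(self, jk: tuple[int, int]) -> bool:
        return self._radius[jk] < self.params.r_min_cm

    def vessel_records(self, limit: int = 200_000) -> list[dict]:
        """Explicit per-vessel records (for inspection and small-tree tests).

        Refuses trees above ``limit`` vessels; the lattice representation
        remains available at any size.
        """
        if self.vessel_count > limit:
            raise ValueError(
                f"tree has {self.vessel_count} vessels; raise limit to enumerate"
            )
        records: list[dict] = []
        stack = [(self.root_radius, 0, -1)]
        while stack:
            r, depth, parent = stack.pop()
            idx = len(records)
            rec = {
                "index": idx,
                "radius": r,
                "length": self.params.lr_ratio * r,
                "depth": depth,
                "parent": parent,
                "daughters": [],
            }
            records.append(rec)
            if parent >= 0:
                records[parent]["daughters"].append(idx)
            if r >= self.params.r_min_cm:
                stack.append((r * self.alpha, depth + 1, idx))
                stack.append((r * self.beta, depth + 1, idx))
        return records


def build_tree(root_radius: float, params: TreeParams) -> StructuredTreeBed:
    """Generate the structured tree below a terminal vessel."""
    return StructuredTreeBed(root_radius, params)


def count_network_vessels(net: ArterialNetwork, params: TreeParams) -> int:
    """Total small-vessel count over every terminal bed of the network."""
    total = 0
    for seg in net.terminal_segments():
        if seg.bed_root_radius is None:
            raise ValueError(f"terminal segment {seg.id} has no bed root radius")
        total += build_tree(seg.bed_root_radius, params).vessel_count
    return total


@dataclass
class ImpedanceSpectrum:
    """Root impedance of a bed over one cardiac period.

    omega : angular frequencies 2 pi k / t_period, k = 0..N/2
    Z     : complex root impedance at those frequencies (CGS)
    z     : real periodic impulse response z(t_j), j = 0..N-1, such that
            P(t) = sum_k z(k dt) Q(t - k dt) dt  over one period
    """

    t_period: float
    N: int
    omega: np.ndarray
    Z: np.ndarray
    z: np.ndarray

    @property
    def dt(self) -> float:
        return self.t_period / self.N

    @property
    def dc_resistance(self) -> float:
        return float(self.Z[0].real)


def _vessel_transfer(
    r0: float,
    length: float,
    omega: np.ndarray,
    Z_distal: np.ndarray,
    tube: TubeLawParams,
) -> np.ndarray:
    """Input impedance of one vessel given its distal impedance.

    Linearized axisymmetric oscillatory flow in a compliant tube: the
    transmission-line solution with Womersley wall-shear factor
    F_J = 2 J1(w0) / (w0 J0(w0)), w0 = i^(3/2) r0 sqrt(omega/nu).
    """
    A0 = math.pi * r0**2
    stiff = wall_stiffness(r0, tube)  # Eh/r0
    C = 3.0 * A0 / (2.0 * stiff)  # area compliance per unit length
    Z_in = np.empty_like(Z_distal)
    # DC: Poiseuille resistance in series
    R_pois = 8.0 * tube.mu * length / (math.pi * r0**4)
    Z_in[0] = Z_distal[0] + R_pois
    w = r0 * np.sqrt(omega[1:] / tube.nu)
    w0 = w * np.exp(1j * 3.0 * math.pi / 4.0)  # i^(3/2) w
    # scaled Bessel ratio is overflow-safe for large |w0|
    F_J = 2.0 * jve(1, w0) / (w0 * jve(0, w0))
    c = np.sqrt(A0 * (1.0 - F_J) / (tube.rho * C))
    g = C * c
    theta = omega[1:] * length / c
    ZL = Z_distal[1:]
    s, co = np.sin(theta), np.cos(theta)
    Z_in[1:] = (1j * s / g + ZL * co) / (co + 1j * g * ZL * s)
    return Z_in


def root_impedance(
    bed: StructuredTreeBed,
    t_period: float,
    N: int,
    tube: TubeLawParams,
) -> ImpedanceSpectrum:
    """Impedance spectrum and periodic impulse response of a bed root.

    The recursion runs leaves-to-root on the scaling lattice; the junction
    condition in the frequency domain is parallel combination of the two
    daughter input impedances.  At omega = 0 this reduces to the
    series/parallel Poiseuille resistance of the whole tree.
    """
    if N < 2 or (N & (N - 1)) != 0:
        raise ValueError("N must be a power of two")
    omega = 2.0 * math.pi * np.arange(N // 2 + 1) / t_period
    z_term = np.full(N // 2 + 1, complex(bed.params.z_terminal))
    memo: dict[tuple[int, int], np.ndarray] = {}
    for jk, r0, _m in bed.lattice():  # deepest (smallest radius) first
        length = bed.params.lr_ratio * r0
        if bed.is_leaf(jk):
            distal = z_term
        else:
            j, k = jk
            Z1, Z2 = memo[(j + 1, k)], memo[(j, k + 1)]
            distal = Z1 * Z2 / (Z1 + Z2)
        Z_in = _vessel_transfer(r0, length, omega, distal, tube)
        if not np.all(np.isfinite(Z_in)):
            bad = int(np.argmax(~np.isfinite(Z_in)))
            raise FloatingPointError(
                f"non-finite impedance at lattice node {jk}, "
                f"frequency index {bad}"
            )
        memo[jk] = Z_in
    Z = memo[(0, 0)]
    if Z[0].real <= 0:
        raise FloatingPointError("non-positive DC impedance")
    # real periodic impulse response via Hermitian inverse DFT
    z = (N / t_period) * np.fft.irfft(Z, n=N)
    return ImpedanceSpectrum(t_period=t_period, N=N, omega=omega, Z=Z, z=z)
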