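"""Structured-tree generation, counting and root impedance."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from lvsa.network_model import TubeLawParams
from lvsa.io_fixtures import make_test_network
from lvsa.structured_tree import (
    TreeParams,
    alpha_beta,
    area_ratio,
    build_tree,
    count_network_vessels,
    root_impedance,
)

TUBE = TubeLawParams()


class TestScalingPair:
    def test_symmetric_bifurcation(self):
        a, b = alpha_beta(3.0, 1.0)
        assert a == pytest.approx(2 ** (-1 / 3), rel=1e-12)
        assert b == pytest.approx(a)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(xi=st.floats(2.33, 3.0), gamma=st.floats(1.0, 6.0))
    def test_defining_identity(self, xi, gamma):
        a, b = alpha_beta(xi, gamma)
        assert 0 < b <= a < 1
        assert a**xi + b**xi == pytest.approx(1.0, abs=1e-12)

    def test_area_ratio_closed_form(self):
        for xi, gamma in ((2.76, 1 / 0.41), (2.5, 2.0), (3.0, 1.0)):
            a, b = alpha_beta(xi, gamma)
            assert a**2 + b**2 == pytest.approx(area_ratio(xi, gamma), abs=1e-10)

    def test_reciprocal_gamma_normalized(self):
        assert alpha_beta(2.76, 0.41) == alpha_beta(2.76, 1 / 0.41)

    def test_warns_outside_usual_exponents(self):
        with pytest.warns(UserWarning):
            TreeParams(xi=2.0)


def _enumerated_counts(root, alpha, beta, r_min):
    """Independent explicit recursion oracle."""
    total = leaves = 0
    stack = [root]
    while stack:
        r = stack.pop()
        total += 1
        if r < r_min:
            leaves += 1
        else:
            stack.extend((alpha * r, beta * r))
    return total, leaves


class TestBuildTree:
    def test_degenerate_single_vessel(self):
        bed = build_tree(0.005, TreeParams())  # below the 100 um cutoff
        assert bed.vessel_count == 1 and bed.leaf_count == 1

    def test_enumeration_example(self):
        # alpha = 0.8, beta = 0.6 realized via xi solving 0.8^xi + 0.6^xi = 1
        xi = brentq(lambda x: 0.8**x + 0.6**x - 1.0, 1.0, 5.0)
        gamma = (0.8 / 0.6) ** 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = TreeParams(xi=xi, gamma=gamma, r_min_um=100.0)
        a, b = alpha_beta(xi, gamma)
        assert (a, b) == (pytest.approx(0.8, abs=1e-12), pytest.approx(0.6, abs=1e-12))
        bed = build_tree(0.0200, params)
        assert bed.vessel_count == 11
        assert bed.leaf_count == 6

    @pytest.mark.parametrize("root", [0.02, 0.05, 0.12])
    def test_counts_match_explicit_recursion(self, root, tree_params):
        bed = build_tree(root, tree_params)
        total, leaves = _enumerated_counts(
            root, bed.alpha, bed.beta, tree_params.r_min_cm
        )
        assert bed.vessel_count == total
        assert bed.leaf_count == leaves
        recs = bed.vessel_records()
        assert len(recs) == total
        assert sum(1 for r in recs if not r["daughters"]) == leaves

    def test_count_monotone_in_xi(self):
        # lowering the radius exponent shrinks alpha/beta and prunes the tree
        counts = [
            build_tree(0.25, TreeParams(xi=xi)).vessel_count
            for xi in (2.4, 2.5, 2.6, 2.76, 2.9)
        ]
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_network_count_and_rarefaction(self):
        net = make_test_network("default24")
        c_base = count_network_vessels(net, TreeParams(xi=2.76))
        c_rare = count_network_vessels(net, TreeParams(xi=2.4))
        assert c_rare < c_base
        # per-bed counts also drop
        for seg in net.terminal_segments():
            nb = build_tree(seg.bed_root_radius, TreeParams(xi=2.76)).vessel_count
            nr = build_tree(seg.bed_root_radius, TreeParams(xi=2.4)).vessel_count
            assert nr < nb


def _dc_resistance_oracle(root, params: TreeParams, tube: TubeLawParams) -> float:
    """Series/parallel Poiseuille recursion by explicit enumeration."""
    a, b = alpha_beta(params.xi, params.gamma)
    mu = tube.mu

    def rec(r):
        own = 8.0 * mu * (params.lr_ratio * r) / (math.pi * r**4)
        if r < params.r_min_cm:
            return own + params.z_terminal
        r1, r2 = rec(a * r), rec(b * r)
        return own + r1 * r2 / (r1 + r2)

    return rec(root)


class TestRootImpedance:
    def test_single_vessel_poiseuille_limit(self):
        params = TreeParams()
        bed = build_tree(0.005, params)  # single vessel
        spec = root_impedance(bed, 0.9, 64, TUBE)
        expect = 8 * TUBE.mu * (params.lr_ratio * 0.005) / (math.pi * 0.005**4)
        assert spec.dc_resistance == pytest.approx(expect, rel=1e-12)

    def test_symmetric_two_level_series_parallel(self):
        # root just above cutoff with gamma = 1: two identical leaf daughters
        params = TreeParams(xi=2.76, gamma=1.0, r_min_um=100.0)
        a, _ = alpha_beta(2.76, 1.0)
        root = 0.0101
        bed = build_tree(root, params)
        assert bed.vessel_count == 3
        spec = root_impedance(bed, 0.9, 64, TUBE)
        R = lambda r: 8 * TUBE.mu * params.lr_ratio * r / (math.pi * r**4)
        assert spec.dc_resistance == pytest.approx(R(root) + R(a * root) / 2, rel=1e-12)

    @pytest.mark.parametrize("root", [0.02, 0.06, 0.18])
    def test_dc_matches_enumeration_oracle(self, root, tree_params):
        bed = build_tree(root, tree_params)
        spec = root_impedance(bed, 0.9, 128, TUBE)
        assert spec.dc_resistance == pytest.approx(
            _dc_resistance_oracle(root, tree_params, TUBE), rel=1e-8
        )

    def test_spectrum_hermitian_and_impulse_real(self, tree_params):
        bed = build_tree(0.15, tree_params)
        spec = root_impedance(bed, 0.9, 256, TUBE)
        assert spec.Z[0].imag == pytest.approx(0.0, abs=1e-12 * abs(spec.Z[0]))
        assert spec.Z[0].real > 0
        # impulse response integrates back to the DC resistance
        assert np.sum(spec.z) * spec.dt == pytest.approx(spec.dc_resistance, rel=1e-10)
        assert np.all(np.isreal(spec.z))

    def test_dc_resistance_responds_to_pruning(self):
        # rarefaction (lower xi) raises the bed resistance; truncating the
        # tree earlier (larger r_min, zero leaf impedance) removes the
        # dominant small-vessel series resistance and lowers it
        base = root_impedance(build_tree(0.2, TreeParams()), 0.9, 64, TUBE)
        truncated = root_impedance(
            build_tree(0.2, TreeParams(r_min_um=150.0)), 0.9, 64, TUBE
        )
        rare = root_impedance(build_tree(0.2, TreeParams(xi=2.4)), 0.9, 64, TUBE)
        assert truncated.dc_resistance < base.dc_resistance
        assert rare.dc_resistance > base.dc_resistance

    def test_power_of_two_required(self, tree_params):
        bed = build_tree(0.05, tree_params)
        with pytest.raises(ValueError):
            root_impedance(bed, 0.9, 100, TUBE)
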