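"""Persistence engines against worked examples and brute-force oracles."""

from __future__ import annotations

import math
from math import inf

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichetda as nt
from nichetda.filtrations import ZigzagSequence, build_fixed_complex, build_intersection_complex
from _oracles import (
    full_reduction_pairs,
    single_linkage_heights,
    zigzag_intervals_bruteforce,
)


def finite_deaths(diagram):
    return sorted(r.death for r in diagram.finite())


class TestPH0:
    def test_two_points_one_edge(self):
        fc = nt.build_vr_filtration([(0, 0), (1, 0)], max_dim=1, max_eps=2.0)
        dgm = nt.ph0(fc)
        assert sorted((r.birth, r.death) for r in dgm.records) == [(0.0, 1.0), (0.0, inf)]

    def test_collinear_merge_heights(self):
        fc = nt.build_vr_filtration([(0, 0), (1, 0), (3, 0)], max_dim=1, max_eps=5.0)
        dgm = nt.ph0(fc)
        assert finite_deaths(dgm) == pytest.approx([1.0, 2.0])
        assert len(dgm.infinite()) == 1

    def test_radial_isolated_points_all_infinite(self):
        pts = [(25 + 30, 25), (25, 25 + 20), (25 - 10, 25)]
        fc = nt.build_radial_filtration(pts, eps=0.5, mu=(25, 25), R=35.0)
        dgm = nt.ph0(fc, "radial")
        assert finite_deaths(dgm) == []
        assert sorted(r.birth for r in dgm.infinite()) == pytest.approx([5.0, 15.0, 25.0])

    def test_one_record_per_point(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (17, 2))
        dgm = nt.ph0(nt.build_vr_filtration(pts, max_dim=1, max_eps=np.inf))
        assert len(dgm.records) == 17

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 40))
    def test_finite_deaths_equal_single_linkage(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, (n, 2))
        dgm = nt.ph0(nt.build_vr_filtration(pts, max_dim=1, max_eps=np.inf))
        assert finite_deaths(dgm) == pytest.approx(single_linkage_heights(pts), abs=1e-9)

    def test_stability_under_jitter(self):
        # perturbing every point by delta moves each finite death by <= 2*delta
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 50, (25, 2))
        delta = 1e-3
        jit = pts + rng.uniform(-delta / math.sqrt(2), delta / math.sqrt(2), pts.shape)
        d0 = finite_deaths(nt.ph0(nt.build_vr_filtration(pts, max_dim=1, max_eps=np.inf)))
        d1 = finite_deaths(nt.ph0(nt.build_vr_filtration(jit, max_dim=1, max_eps=np.inf)))
        assert np.max(np.abs(np.array(d0) - np.array(d1))) <= 2 * delta


class TestPH1:
    def test_unit_square(self):
        fc = nt.build_vr_filtration([(0, 0), (1, 0), (1, 1), (0, 1)], max_dim=2, max_eps=2.0)
        bars = [(r.birth, r.death) for r in nt.ph1(fc).records]
        assert len(bars) == 1
        assert bars[0] == pytest.approx((1.0, math.sqrt(2)))

    def test_triangle_has_no_h1(self):
        fc = nt.build_vr_filtration([(0, 0), (1, 0), (0, 1)], max_dim=2, max_eps=2.0)
        assert nt.ph1(fc).records == []

    def test_regular_hexagon(self):
        pts = [(math.cos(k * math.pi / 3), math.sin(k * math.pi / 3)) for k in range(6)]
        bars = [(r.birth, r.death) for r in nt.ph1(nt.build_vr_filtration(pts, 2, 3.0)).records]
        assert len(bars) == 1
        assert bars[0] == pytest.approx((1.0, math.sqrt(3)))

    def test_truncated_cycle_reported_infinite(self):
        pts = [(math.cos(k * math.pi / 3), math.sin(k * math.pi / 3)) for k in range(6)]
        dgm = nt.ph1(nt.build_vr_filtration(pts, max_dim=2, max_eps=1.2))
        assert [(r.birth, r.death) for r in dgm.records] == [(pytest.approx(1.0), inf)]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 15))
    def test_matches_full_reduction_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (n, 2))
        fc = nt.build_vr_filtration(pts, max_dim=2, max_eps=6.0)
        ours = sorted((r.birth, r.death) for r in nt.ph1(fc).records)
        oracle = full_reduction_pairs(fc)[1]
        assert len(ours) == len(oracle)
        for a, b in zip(ours, oracle):
            assert a == pytest.approx(b)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(3, 12))
    def test_euler_characteristic_at_full_scale(self, seed, n):
        # V - E + T of the final complex equals b0 - b1 + b2; with no
        # 3-simplices b2 is the GF(2) corank of the triangle boundary matrix
        from _oracles import _gf2_rank

        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (n, 2))
        fc = nt.build_vr_filtration(pts, max_dim=2, max_eps=4.0)
        h0_alive = len(nt.ph0(fc).infinite())
        h1_alive = len(nt.ph1(fc).infinite())
        edge_idx = {(int(a), int(b)): k for k, (a, b) in enumerate(fc.edges)}
        boundary = np.zeros((fc.n_edges, fc.n_triangles), dtype=np.uint8)
        for col, (a, b, c) in enumerate(fc.triangles):
            for u, v in ((a, b), (a, c), (b, c)):
                boundary[edge_idx[(int(u), int(v))], col] = 1
        h2_alive = fc.n_triangles - (_gf2_rank(boundary) if fc.n_triangles else 0)
        euler = fc.n_points - fc.n_edges + fc.n_triangles
        assert h0_alive - h1_alive + h2_alive == euler


def make_sequence(clouds, eps):
    """clouds: list of (ids, points); returns the alternating zigzag."""
    snaps = [build_fixed_complex(xy, eps, max_dim=2, ids=ids) for ids, xy in clouds]
    complexes = []
    for i, k in enumerate(snaps):
        if i:
            complexes.append(build_intersection_complex(snaps[i - 1], k))
        complexes.append(k)
    return ZigzagSequence(complexes, float(eps), list(range(0, 10 * len(snaps), 10)))


class TestZigzagPH0:
    def test_single_complex_components(self):
        seq = make_sequence([(np.arange(3), np.array([[0, 0], [5, 0], [10, 0]]))], eps=1.0)
        assert nt.zigzag_ph0(seq).intervals == [(0, 0, 3)]

    def test_static_components_span(self):
        cloud = (np.arange(3), np.array([[0.0, 0], [5, 0], [10, 0]]))
        seq = make_sequence([cloud, cloud], eps=1.0)
        assert nt.zigzag_ph0(seq).intervals == [(0, 2, 3)]

    def test_split_born_at_intersection(self):
        # two cells linked at t, separated at t+10: [0,2] plus [1,2]
        seq = make_sequence(
            [(np.array([1, 2]), np.array([[0.0, 0], [1, 0]])),
             (np.array([1, 2]), np.array([[0.0, 0], [3, 0]]))],
            eps=1.5,
        )
        assert nt.zigzag_ph0(seq).intervals == [(0, 2, 1), (1, 2, 1)]

    def test_split_then_remerge(self):
        linked = (np.array([1, 2]), np.array([[0.0, 0], [1, 0]]))
        apart = (np.array([1, 2]), np.array([[0.0, 0], [3, 0]]))
        seq = make_sequence([linked, apart, linked], eps=1.5)
        assert nt.zigzag_ph0(seq).intervals == [(0, 4, 1), (1, 3, 1)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_multiplicity_invariant_and_oracle_on_random_dynamics(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        k = int(rng.integers(2, 5))
        ids = np.arange(n)
        clouds = []
        xy = rng.uniform(0, 6, (n, 2))
        for _ in range(k):
            keep = rng.random(n) > 0.15
            clouds.append((ids[keep], xy[keep]))
            xy = xy + rng.normal(0, 1.2, xy.shape)
        seq = make_sequence(clouds, eps=2.0)
        result = nt.zigzag_ph0(seq)
        # per-index multiplicities equal component counts
        from _oracles import _zigzag_spaces

        comps, _ = _zigzag_spaces(seq)
        for idx in range(len(seq)):
            assert result.multiplicity_at(idx) == len(comps[idx])
        # full interval decomposition matches GF(2) linear-algebra oracle
        assert sorted(result.intervals) == zigzag_intervals_bruteforce(seq)
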