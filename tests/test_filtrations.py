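"""Complex constructions: VR, fixed-radius, radial, intersection, zigzag, transport."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichetda as nt
from nichetda.filtrations import build_single_linkage_filtration


def simplex_set(fc):
    return {s.vertices for s in fc.simplices()}


def value_of(fc, verts):
    for s in fc.simplices():
        if s.vertices == verts:
            return s.value
    raise KeyError(verts)


class TestVietorisRips:
    def test_right_triangle_edges_and_triangle(self):
        fc = nt.build_vr_filtration([(0, 0), (1, 0), (0, 1)], max_dim=2, max_eps=2.0)
        assert value_of(fc, (0, 1)) == pytest.approx(1.0)
        assert value_of(fc, (0, 2)) == pytest.approx(1.0)
        assert value_of(fc, (1, 2)) == pytest.approx(math.sqrt(2))
        assert value_of(fc, (0, 1, 2)) == pytest.approx(math.sqrt(2))
        assert fc.n_triangles == 1

    def test_single_point_and_empty(self):
        fc = nt.build_vr_filtration([(3, 4)], max_dim=2, max_eps=1.0)
        assert simplex_set(fc) == {(0,)}
        empty = nt.build_vr_filtration(np.empty((0, 2)), max_dim=2, max_eps=1.0)
        assert empty.n_points == 0 and empty.n_edges == 0

    def test_truncation_omits_long_edges(self):
        fc = nt.build_vr_filtration([(0, 0), (3, 0)], max_dim=2, max_eps=2.0)
        assert simplex_set(fc) == {(0,), (1,)}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 12))
    def test_face_closure_and_value_monotonicity(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (n, 2))
        fc = nt.build_vr_filtration(pts, max_dim=2, max_eps=4.0)
        values = {s.vertices: s.value for s in fc.simplices()}
        for verts, v in values.items():
            for face in itertools.combinations(verts, len(verts) - 1):
                if face:
                    assert face in values
                    assert values[face] <= v + 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 12))
    def test_thresholded_vr_equals_fixed_complex(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (n, 2))
        eps = 3.0
        vr = nt.build_vr_filtration(pts, max_dim=2, max_eps=eps)
        fixed = nt.build_fixed_complex(pts, eps, max_dim=2)
        assert simplex_set(vr) == simplex_set(fixed)
        assert all(s.value == 0.0 for s in fixed.simplices())


class TestFixedComplex:
    def test_full_triangle_when_mutually_close(self):
        fc = nt.build_fixed_complex([(0, 0), (1, 0), (0.5, 0.8)], eps=1.5, max_dim=2)
        assert (0, 1, 2) in simplex_set(fc)

    def test_chain_without_triangle(self):
        fc = nt.build_fixed_complex([(0, 0), (1, 0), (2, 0)], eps=1.2, max_dim=2)
        s = simplex_set(fc)
        assert (0, 1) in s and (1, 2) in s and (0, 2) not in s and (0, 1, 2) not in s

    def test_empty_points(self):
        fc = nt.build_fixed_complex(np.empty((0, 2)), eps=1.0)
        assert fc.n_points == 0


class TestRadialFiltration:
    def test_isolated_points_values(self):
        mu = (25.0, 25.0)
        pts = [(25 + 30, 25), (25, 25 + 20), (25 - 10, 25)]
        fc = nt.build_radial_filtration(pts, eps=0.5, mu=mu, R=35.0)
        assert fc.n_edges == 0
        assert sorted(fc.vertex_values) == pytest.approx([5.0, 15.0, 25.0])

    def test_edge_value_is_max_of_vertices(self):
        mu = (0.0, 0.0)
        pts = [(10.0, 0.0), (10.5, 0.0)]
        fc = nt.build_radial_filtration(pts, eps=1.0, mu=mu, R=35.0)
        assert fc.n_edges == 1
        assert fc.edge_values[0] == pytest.approx(35.0 - 10.0)

    def test_point_at_basepoint_enters_last(self):
        fc = nt.build_radial_filtration([(25.0, 25.0)], eps=1.0, mu=(25, 25), R=35.0)
        assert fc.vertex_values[0] == pytest.approx(35.0)

    def test_point_outside_R_raises(self):
        with pytest.raises(ValueError, match="maximum radius"):
            nt.build_radial_filtration([(70.0, 25.0)], eps=1.0, mu=(25, 25), R=35.0)


class TestIntersectionComplex:
    def make(self, pts, ids, eps=1.5):
        return nt.build_fixed_complex(pts, eps, max_dim=2, ids=ids)

    def test_self_intersection_idempotent(self):
        k = self.make([(0, 0), (1, 0), (0.5, 0.8)], [4, 7, 9])
        inter = nt.build_intersection_complex(k, k)
        assert simplex_set(inter) == simplex_set(k)

    def test_moved_apart_drops_edge_keeps_vertices(self):
        k1 = self.make([(0, 0), (1, 0)], [1, 2])
        k2 = self.make([(0, 0), (5, 0)], [1, 2])
        inter = nt.build_intersection_complex(k1, k2)
        assert simplex_set(inter) == {(0,), (1,)}

    def test_departed_cell_absent(self):
        k1 = self.make([(0, 0), (1, 0)], [1, 2])
        k2 = self.make([(0, 0)], [1])
        inter = nt.build_intersection_complex(k1, k2)
        assert inter.n_points == 1 and list(inter.vertex_ids) == [1]

    def test_epsilon_mismatch_raises(self):
        k1 = self.make([(0, 0)], [1], eps=1.0)
        k2 = self.make([(0, 0)], [1], eps=2.0)
        with pytest.raises(ValueError, match="epsilon"):
            nt.build_intersection_complex(k1, k2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_commutative_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        ids = np.arange(8)
        k1 = self.make(rng.uniform(0, 5, (8, 2)), ids)
        k2 = self.make(rng.uniform(0, 5, (8, 2)), ids)
        i12 = nt.build_intersection_complex(k1, k2)
        i21 = nt.build_intersection_complex(k2, k1)
        id_simplices = lambda k: {
            tuple(sorted(int(k.vertex_ids[v]) for v in s.vertices)) for s in k.simplices()
        }
        assert id_simplices(i12) == id_simplices(i21)
        assert id_simplices(i12) <= id_simplices(k1)


class TestZigzagSequence:
    def test_length_19_for_10_snapshots(self, short_run):
        times = list(range(100, 200, 10))
        seq = nt.build_zigzag_sequence(short_run, "macrophage", 2.0, times)
        assert len(seq) == 19

    def test_k1_single_complex(self, short_run):
        seq = nt.build_zigzag_sequence(short_run, "tumour", 0.7, [100])
        assert len(seq) == 1

    def test_static_points_give_identical_complexes(self):
        from nichetda.synthetic_abm import CellTimeSeries, Snapshot

        xy = np.array([[1.0, 1.0], [1.5, 1.0], [10.0, 10.0]])
        ids = np.array([3, 4, 5])
        snaps = [
            Snapshot(t, np.empty(0, int), np.empty((0, 2)), ids, xy.copy(), np.zeros(3),
                     np.array([0]), np.array([[25.0, 25.0]]))
            for t in (0, 10, 20)
        ]
        series = CellTimeSeries(snaps)
        seq = nt.build_zigzag_sequence(series, "macrophage", 1.0, [0, 10, 20])
        assert len(seq) == 5
        base = {
            tuple(sorted(int(seq.complexes[0].vertex_ids[v] ) for v in s.vertices))
            for s in seq.complexes[0].simplices()
        }
        for k in seq.complexes[1:]:
            ids_set = {
                tuple(sorted(int(k.vertex_ids[v]) for v in s.vertices)) for s in k.simplices()
            }
            assert ids_set == base

    def test_missing_timestep_named(self, short_run):
        with pytest.raises(ValueError, match="135"):
            nt.build_zigzag_sequence(short_run, "macrophage", 2.0, [130, 135])


class TestSingleLinkageFiltration:
    def test_same_h0_as_full_vr(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 20, (25, 2))
        full = nt.ph0(nt.build_vr_filtration(pts, max_dim=1, max_eps=np.inf))
        sparse = nt.ph0(build_single_linkage_filtration(pts))
        d1 = sorted(r.death for r in full.finite())
        d2 = sorted(r.death for r in sparse.finite())
        assert d1 == pytest.approx(d2)
        assert len(sparse.infinite()) == 1


class TestTransportMatching:
    def test_identity_matching(self):
        pts = np.array([[0.0, 0.0], [3.0, 1.0]])
        m = nt.match_cells_by_transport(pts, pts, np.array([[25.0, 25.0]]))
        assert list(m.forward) == [0, 1]
        assert m.cost == pytest.approx(0.0)

    def test_single_moved_point_cost(self):
        m = nt.match_cells_by_transport(
            np.array([[0.0, 0.0]]), np.array([[0.3, 0.4]]), np.empty((0, 2))
        )
        assert list(m.forward) == [0]
        assert m.cost == pytest.approx(0.5**2)

    def test_departed_point_matches_nearest_vessel(self):
        vessels = np.array([[10.0, 0.0], [0.0, 10.0]])
        p1 = np.array([[9.0, 0.5], [0.0, 0.0]])
        p2 = np.array([[0.1, 0.1]])
        m = nt.match_cells_by_transport(p1, p2, vessels)
        assert m.forward[0] == -1  # vessel 0 is nearest
        assert m.forward[1] == 0

    def test_minimality_against_bruteforce(self):
        # exhaustive over all matchings on <= 4 + 3 points with vessel slots
        rng = np.random.default_rng(11)
        p1 = rng.uniform(0, 5, (4, 2))
        p2 = rng.uniform(0, 5, (3, 2))
        vessels = rng.uniform(0, 5, (2, 2))
        from scipy.spatial.distance import cdist

        v1 = (cdist(p1, vessels) ** 2).min(axis=1)
        v2 = (cdist(p2, vessels) ** 2).min(axis=1)
        dd = cdist(p1, p2) ** 2
        best = np.inf
        for k in range(min(len(p1), len(p2)) + 1):
            for sub1 in itertools.combinations(range(len(p1)), k):
                for sub2 in itertools.permutations(range(len(p2)), k):
                    c = sum(dd[i, j] for i, j in zip(sub1, sub2))
                    c += sum(v1[i] for i in range(len(p1)) if i not in sub1)
                    c += sum(v2[j] for j in range(len(p2)) if j not in sub2)
                    best = min(best, c)
        m = nt.match_cells_by_transport(p1, p2, vessels)
        assert m.cost == pytest.approx(best)
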