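"""Simplicial complex constructions on 2-D cell point clouds.

Four constructions feed the persistence computations:

* Vietoris-Rips filtrations (edges at their pairwise distance, triangles at
  the maximum of their edge values), truncated at a maximum radius;
* fixed-radius ("static") VR complexes, used as snapshots in zigzags;
* radial filtrations: the fixed-radius complex filtered by distance from a
  basepoint, outermost cells entering first;
* intersection complexes between consecutive snapshots, matched by cell
  identity, which turn a sequence of static complexes into a zigzag.

Distances are Euclidean and the VR convention uses closed balls: an edge
appears exactly at d(x, y).  Simplices sharing a filtration value are ordered
by dimension and then lexicographically by vertex tuple, which makes every
construction deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist, squareform


@dataclass(frozen=True)
class Simplex:
    """A simplex of dimension 0-2 with its filtration value."""

    vertices: tuple[int, ...]
    value: float

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.vertices, self.vertices[1:])):
            raise ValueError(f"simplex vertices must be strictly increasing: {self.vertices}")

    @property
    def dimension(self) -> int:
        return len(self.vertices) - 1


@dataclass
class FilteredComplex:
    """A filtered simplicial complex of dimension at most 2.

    Vertices are indexed ``0 .. n_points-1``; ``vertex_ids`` optionally carries
    stable cell identities so that complexes from different snapshots can be
    intersected.  ``epsilon`` records the linkage radius for fixed-radius
    complexes (``None`` for genuine VR filtrations).
    """

    n_points: int
    vertex_values: np.ndarray
    edges: np.ndarray
    edge_values: np.ndarray
    triangles: np.ndarray
    triangle_values: np.ndarray
    max_dimension: int = 2
    vertex_ids: np.ndarray | None = None
    epsilon: float | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edge_values)

    @property
    def n_triangles(self) -> int:
        return len(self.triangle_values)

    def simplices(self) -> list[Simplex]:
        """All simplices in filtration order (value, dimension, vertex tuple)."""
        out = [Simplex((int(i),), float(v)) for i, v in enumerate(self.vertex_values)]
        out += [
            Simplex((int(e[0]), int(e[1])), float(v))
            for e, v in zip(self.edges, self.edge_values)
        ]
        out += [
            Simplex((int(t[0]), int(t[1]), int(t[2])), float(v))
            for t, v in zip(self.triangles, self.triangle_values)
        ]
        return sorted(out, key=lambda s: (s.value, s.dimension, s.vertices))


def _empty_complex(max_dim: int, epsilon: float | None = None) -> FilteredComplex:
    return FilteredComplex(
        n_points=0,
        vertex_values=np.empty(0),
        edges=np.empty((0, 2), dtype=np.intp),
        edge_values=np.empty(0),
        triangles=np.empty((0, 3), dtype=np.intp),
        triangle_values=np.empty(0),
        max_dimension=max_dim,
        vertex_ids=np.empty(0, dtype=np.intp),
        epsilon=epsilon,
    )


def _edges_triangles(points: np.ndarray, eps: float, max_dim: int):
    """Edge list, edge lengths and (optionally) triangles of the eps-neighbour graph."""
    n = len(points)
    dm = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))
    adj = dm <= eps
    np.fill_diagonal(adj, False)
    iu, ju = np.where(np.triu(adj))
    edges = np.column_stack([iu, ju]).astype(np.intp)
    edge_values = dm[iu, ju]
    triangles = np.empty((0, 3), dtype=np.intp)
    triangle_values = np.empty(0)
    if max_dim >= 2 and len(edges):
        tri_list = []
        val_list = []
        for (i, j), dij in zip(edges, edge_values):
            common = np.where(adj[i] & adj[j])[0]
            ks = common[common > j]
            if len(ks):
                tri_list.append(np.column_stack([np.full(len(ks), i), np.full(len(ks), j), ks]))
                val_list.append(np.maximum(dij, np.maximum(dm[i, ks], dm[j, ks])))
        if tri_list:
            triangles = np.vstack(tri_list).astype(np.intp)
            triangle_values = np.concatenate(val_list)
    return dm, edges, edge_values, triangles, triangle_values


def build_vr_filtration(
    points: np.ndarray, max_dim: int = 1, max_eps: float = np.inf
) -> FilteredComplex:
    """Vietoris-Rips filtration of a 2-D point cloud, truncated at ``max_eps``.

    Vertices enter at 0, an edge at the distance between its endpoints, and a
    triangle at the largest of its edge values; simplices whose value exceeds
    ``max_eps`` are omitted.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if not 0 <= max_dim <= 2:
        raise ValueError("max_dim must be 0, 1 or 2")
    if len(points) == 0:
        return _empty_complex(max_dim)
    _, edges, ev, tris, tv = _edges_triangles(points, max_eps, max_dim)
    if max_dim == 0:
        edges, ev = np.empty((0, 2), dtype=np.intp), np.empty(0)
    return FilteredComplex(
        n_points=len(points),
        vertex_values=np.zeros(len(points)),
        edges=edges,
        edge_values=ev,
        triangles=tris,
        triangle_values=tv,
        max_dimension=max_dim,
    )


def build_fixed_complex(
    points: np.ndarray,
    eps: float,
    max_dim: int = 2,
    ids: np.ndarray | None = None,
) -> FilteredComplex:
    """Static VR complex at linkage radius ``eps`` with all filtration values 0.

    ``ids`` attaches stable cell identities to the vertices, enabling
    intersection complexes between snapshots.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if ids is None:
        ids = np.arange(len(points), dtype=np.intp)
    else:
        ids = np.asarray(ids, dtype=np.intp)
        if len(ids) != len(points):
            raise ValueError("ids and points length mismatch")
    if len(points) == 0:
        return _empty_complex(max_dim, epsilon=float(eps))
    _, edges, _, tris, _ = _edges_triangles(points, eps, max_dim)
    if max_dim == 0:
        edges = np.empty((0, 2), dtype=np.intp)
    if max_dim < 2:
        tris = np.empty((0, 3), dtype=np.intp)
    return FilteredComplex(
        n_points=len(points),
        vertex_values=np.zeros(len(points)),
        edges=edges,
        edge_values=np.zeros(len(edges)),
        triangles=tris,
        triangle_values=np.zeros(len(tris)),
        max_dimension=max_dim,
        vertex_ids=ids,
        epsilon=float(eps),
    )


def build_radial_filtration(
    points: np.ndarray, eps: float, mu=(25.0, 25.0), R: float = 35.0
) -> FilteredComplex:
    """Radial filtration: the eps-complex filtered by distance from basepoint ``mu``.

    A vertex at distance ``r`` from the basepoint has filtration value
    ``R - r``, so the outermost cells enter first and the filtration runs from
    0 to R; edges and triangles enter with the latest of their vertices.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    mu = np.asarray(mu, dtype=float)
    if len(points) == 0:
        return _empty_complex(2, epsilon=float(eps))
    radial = np.linalg.norm(points - mu, axis=1)
    if np.any(radial >= R):
        bad = int(np.argmax(radial))
        raise ValueError(
            f"point {bad} at distance {radial[bad]:.3f} from basepoint is not "
            f"strictly inside the maximum radius R={R}"
        )
    fixed = build_fixed_complex(points, eps, max_dim=2)
    vvals = R - radial
    evals = np.maximum(vvals[fixed.edges[:, 0]], vvals[fixed.edges[:, 1]]) if fixed.n_edges else np.empty(0)
    if fixed.n_triangles:
        tvals = np.maximum(
            vvals[fixed.triangles[:, 0]],
            np.maximum(vvals[fixed.triangles[:, 1]], vvals[fixed.triangles[:, 2]]),
        )
    else:
        tvals = np.empty(0)
    return FilteredComplex(
        n_points=len(points),
        vertex_values=vvals,
        edges=fixed.edges,
        edge_values=evals,
        triangles=fixed.triangles,
        triangle_values=tvals,
        max_dimension=2,
        epsilon=float(eps),
    )


def build_intersection_complex(k1: FilteredComplex, k2: FilteredComplex) -> FilteredComplex:
    """Simplices present (by cell-id tuple) in both fixed-radius complexes."""
    if k1.epsilon is None or k2.epsilon is None or k1.epsilon != k2.epsilon:
        raise ValueError(f"epsilon mismatch between complexes: {k1.epsilon} vs {k2.epsilon}")
    if k1.vertex_ids is None or k2.vertex_ids is None:
        raise ValueError("intersection requires complexes with vertex_ids")
    common = np.intersect1d(k1.vertex_ids, k2.vertex_ids)
    if len(common) == 0:
        return _empty_complex(min(k1.max_dimension, k2.max_dimension), epsilon=k1.epsilon)
    local = {int(cid): idx for idx, cid in enumerate(common)}

    def _id_simplices(k: FilteredComplex, simp: np.ndarray) -> set[tuple[int, ...]]:
        out = set()
        for row in simp:
            ids = tuple(sorted(int(k.vertex_ids[v]) for v in row))
            out.add(ids)
        return out

    shared_edges = sorted(_id_simplices(k1, k1.edges) & _id_simplices(k2, k2.edges))
    shared_tris = sorted(_id_simplices(k1, k1.triangles) & _id_simplices(k2, k2.triangles))
    # keep only simplices whose vertices all survive (they do by construction:
    # an edge present in both complexes has both endpoints in both)
    edges = np.array([[local[a], local[b]] for a, b in shared_edges], dtype=np.intp).reshape(-1, 2)
    edges = np.sort(edges, axis=1)
    tris = np.array(
        [[local[a], local[b], local[c]] for a, b, c in shared_tris], dtype=np.intp
    ).reshape(-1, 3)
    tris = np.sort(tris, axis=1)
    return FilteredComplex(
        n_points=len(common),
        vertex_values=np.zeros(len(common)),
        edges=edges,
        edge_values=np.zeros(len(edges)),
        triangles=tris,
        triangle_values=np.zeros(len(tris)),
        max_dimension=min(k1.max_dimension, k2.max_dimension),
        vertex_ids=common.astype(np.intp),
        epsilon=k1.epsilon,
    )


def build_single_linkage_filtration(points: np.ndarray) -> FilteredComplex:
    """Edge-reduced VR filtration with the same dimension-0 persistence.

    Keeps only the edges of a Euclidean minimum spanning tree: single-linkage
    merge heights — and hence every dimension-0 birth and death of the full,
    untruncated VR filtration — are preserved exactly, while the edge count
    drops from O(n^2) to n - 1.  Only valid for dimension-0 computations.
    """
    from scipy.sparse.csgraph import minimum_spanning_tree

    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n == 0:
        return _empty_complex(0)
    if n == 1:
        return build_vr_filtration(points, max_dim=0)
    dm = squareform(pdist(points))
    # coincident points: keep their zero-length edge visible to the sparse MST
    dm[dm == 0] = 1e-12
    np.fill_diagonal(dm, 0.0)
    mst = minimum_spanning_tree(dm).tocoo()
    edges = np.sort(np.column_stack([mst.row, mst.col]).astype(np.intp), axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return FilteredComplex(
        n_points=n,
        vertex_values=np.zeros(n),
        edges=edges[order],
        edge_values=dm[edges[order, 0], edges[order, 1]],
        triangles=np.empty((0, 3), dtype=np.intp),
        triangle_values=np.empty(0),
        max_dimension=1,
    )


@dataclass
class ZigzagSequence:
    """Alternating snapshot/intersection complexes over a shared cell-id universe.

    For k snapshot times the sequence has length 2k-1: even indices hold the
    snapshot complexes, odd indices the intersections of their neighbours, and
    each odd complex includes into the complexes on either side.
    """

    complexes: list[FilteredComplex]
    epsilon: float
    times: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)


def build_zigzag_sequence(series, cell_type: str, eps: float, times) -> ZigzagSequence:
    """Build the length-2k-1 zigzag of fixed-radius complexes for ``times``.

    ``series`` is a :class:`~nichetda.synthetic_abm.CellTimeSeries`; cells are
    matched across snapshots by their stable ``cell_id``.
    """
    times = [int(t) for t in times]
    snaps = []
    for t in times:
        snap = series.snapshot_at(t)
        if snap is None:
            raise ValueError(f"missing timestep {t} in series")
        ids, xy = snap.points_of_type(cell_type)
        snaps.append(build_fixed_complex(xy, eps, max_dim=2, ids=ids))
    complexes: list[FilteredComplex] = []
    for idx, k in enumerate(snaps):
        if idx > 0:
            complexes.append(build_intersection_complex(snaps[idx - 1], k))
        complexes.append(k)
    return ZigzagSequence(complexes=complexes, epsilon=float(eps), times=times)


@dataclass
class TransportMatching:
    """Minimum squared-displacement matching between two snapshots.

    ``forward[i]`` is the index in the second cloud matched to point ``i`` of
    the first, or ``-(k+1)`` when point ``i`` is matched to vessel ``k``;
    ``backward`` is the same for the second cloud.  Vessels may be reused with
    arbitrary multiplicity.
    """

    forward: np.ndarray
    backward: np.ndarray
    cost: float


def match_cells_by_transport(
    points_t: np.ndarray, points_t2: np.ndarray, vessel_points: np.ndarray
) -> TransportMatching:
    """Match unlabelled cells across a time step by minimising total squared displacement.

    Solved as a balanced assignment problem in which every cell may instead
    pair with its nearest blood vessel (cells entering or re-entering the
    vasculature), so vessels act as sources and sinks of unlimited capacity.
    """
    p1 = np.asarray(points_t, dtype=float).reshape(-1, 2)
    p2 = np.asarray(points_t2, dtype=float).reshape(-1, 2)
    vs = np.asarray(vessel_points, dtype=float).reshape(-1, 2)
    n1, n2 = len(p1), len(p2)
    big = 1e18
    if len(vs):
        v1 = (cdist(p1, vs) ** 2).min(axis=1) if n1 else np.empty(0)
        v2 = (cdist(p2, vs) ** 2).min(axis=1) if n2 else np.empty(0)
        v1_arg = (cdist(p1, vs) ** 2).argmin(axis=1) if n1 else np.empty(0, dtype=int)
        v2_arg = (cdist(p2, vs) ** 2).argmin(axis=1) if n2 else np.empty(0, dtype=int)
    else:
        v1 = np.full(n1, big)
        v2 = np.full(n2, big)
        v1_arg = np.zeros(n1, dtype=int)
        v2_arg = np.zeros(n2, dtype=int)
    size = n1 + n2
    cost = np.zeros((size, size))
    if n1 and n2:
        cost[:n1, :n2] = cdist(p1, p2) ** 2
    cost[:n1, n2:] = v1[:, None]  # real point -> vessel sink
    cost[n1:, :n2] = v2[None, :]  # vessel source -> real point
    cost[n1:, n2:] = 0.0  # unused vessel source -> vessel sink
    rows, cols = linear_sum_assignment(cost)
    forward = np.empty(n1, dtype=np.intp)
    backward = np.empty(n2, dtype=np.intp)
    total = 0.0
    for r, c in zip(rows, cols):
        if r < n1 and c < n2:
            forward[r] = c
            backward[c] = r
            total += cost[r, c]
        elif r < n1:
            forward[r] = -(int(v1_arg[r]) + 1)
            total += cost[r, c]
        elif c < n2:
            backward[c] = -(int(v2_arg[c]) + 1)
            total += cost[r, c]
    return TransportMatching(forward=forward, backward=backward, cost=float(total))
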