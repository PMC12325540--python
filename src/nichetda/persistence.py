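"""Persistent homology of filtered complexes and zigzag sequences.

Everything is computed over the field with two elements.

* ``ph0`` runs union-find with the elder rule over the filtration order; on a
  VR filtration its finite deaths coincide with single-linkage dendrogram
  merge heights, which is the oracle used in the test suite.
* ``ph1`` reduces the triangle boundary matrix, with columns stored as Python
  integers used as bitsets over edge indices; edges that create cycles and are
  never paired with a triangle yield infinite dimension-1 bars.
* ``zigzag_ph0`` decomposes the dimension-0 zigzag module of an alternating
  snapshot/intersection sequence.  Because every structure map is induced by a
  map of connected components, the generalized rank of the module over a
  segment [i, j] equals the number of connected components of the segment's
  component telescope (components at each index, glued along the structure
  maps) that meet *every* index of the segment.  Interval multiplicities then
  follow from the standard four-term inclusion-exclusion on interval ranks.
  A left-to-right sweep with a fixed assignment of births to components is
  *not* used: at a component split the fragment that should inherit the older
  birth depends on the future of the sequence, so no online rule is correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np

from .filtrations import FilteredComplex, ZigzagSequence


@dataclass(frozen=True)
class DiagramRecord:
    """A (birth, death) feature; ``death`` may be ``math.inf``."""

    dimension: int
    birth: float
    death: float
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.dimension not in (0, 1):
            raise ValueError("dimension must be 0 or 1")
        if self.birth > self.death:
            raise ValueError(f"birth {self.birth} exceeds death {self.death}")

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    records: list[DiagramRecord]
    filtration_kind: str = "vr"
    axis_units: str = "length"

    def finite(self) -> list[DiagramRecord]:
        return [r for r in self.records if r.death != inf]

    def infinite(self) -> list[DiagramRecord]:
        return [r for r in self.records if r.death == inf]

    def in_dimension(self, dim: int) -> list[DiagramRecord]:
        return [r for r in self.records if r.dimension == dim]


class _UnionFind:
    """Union-find tracking (birth, smallest member vertex) per component root."""

    def __init__(self, births: np.ndarray):
        n = len(births)
        self.parent = list(range(n))
        self.birth = list(map(float, births))
        self.min_vertex = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int):
        """Merge; return (dying_birth, surviving_root) or None if already joined."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        # elder rule: the younger component (later birth) dies; ties broken so
        # that the component containing the smaller vertex index survives
        key_a = (self.birth[ra], self.min_vertex[ra])
        key_b = (self.birth[rb], self.min_vertex[rb])
        survivor, dying = (ra, rb) if key_a <= key_b else (rb, ra)
        dying_birth = self.birth[dying]
        self.parent[dying] = survivor
        self.min_vertex[survivor] = min(self.min_vertex[survivor], self.min_vertex[dying])
        return dying_birth, survivor


def _sorted_edge_order(filtration: FilteredComplex) -> np.ndarray:
    if filtration.n_edges == 0:
        return np.empty(0, dtype=np.intp)
    keys = list(zip(filtration.edge_values, filtration.edges[:, 0], filtration.edges[:, 1]))
    return np.array(sorted(range(len(keys)), key=lambda i: keys[i]), dtype=np.intp)


def ph0(filtration: FilteredComplex, filtration_kind: str = "vr") -> PersistenceDiagram:
    """Dimension-0 persistence: one record per point, infinite bars for
    components alive at the end of the filtration."""
    n = filtration.n_points
    records: list[DiagramRecord] = []
    if n == 0:
        return PersistenceDiagram([], filtration_kind=filtration_kind)
    uf = _UnionFind(filtration.vertex_values)
    for ei in _sorted_edge_order(filtration):
        a, b = map(int, filtration.edges[ei])
        merged = uf.union(a, b)
        if merged is not None:
            dying_birth, _ = merged
            records.append(DiagramRecord(0, dying_birth, float(filtration.edge_values[ei])))
    seen_roots = set()
    for v in range(n):
        r = uf.find(v)
        if r not in seen_roots:
            seen_roots.add(r)
            records.append(DiagramRecord(0, uf.birth[r], inf))
    records.sort(key=lambda r: (r.birth, r.death))
    return PersistenceDiagram(records, filtration_kind=filtration_kind)


def ph1(filtration: FilteredComplex, filtration_kind: str = "vr") -> PersistenceDiagram:
    """Dimension-1 persistence by mod-2 reduction of the triangle boundary matrix.

    Zero-persistence pairs are not reported; 1-cycles never filled by a
    triangle are reported with infinite death.
    """
    m = filtration.n_edges
    records: list[DiagramRecord] = []
    if m == 0:
        return PersistenceDiagram([], filtration_kind=filtration_kind)
    edge_order = _sorted_edge_order(filtration)
    edge_rank = {int(ei): rank for rank, ei in enumerate(edge_order)}
    # edges that do not merge two components create 1-cycles ("positive" edges)
    uf = _UnionFind(filtration.vertex_values)
    positive = np.zeros(m, dtype=bool)
    for ei in edge_order:
        a, b = map(int, filtration.edges[ei])
        if uf.union(a, b) is None:
            positive[ei] = True

    # map vertex pair -> edge index for triangle boundaries
    pair_to_edge = {
        (int(a), int(b)): int(ei) for ei, (a, b) in enumerate(filtration.edges)
    }
    tris = filtration.triangles
    tvals = filtration.triangle_values
    tri_order = sorted(
        range(len(tvals)), key=lambda i: (tvals[i], tuple(int(v) for v in tris[i]))
    )
    pivot: dict[int, int] = {}  # edge rank -> reduced column bitset
    edge_value_by_rank = [float(filtration.edge_values[ei]) for ei in edge_order]
    paired_rank: set[int] = set()
    for ti in tri_order:
        a, b, c = map(int, tris[ti])
        col = 0
        for u, v in ((a, b), (a, c), (b, c)):
            col |= 1 << edge_rank[pair_to_edge[(u, v)]]
        while col:
            low = col.bit_length() - 1
            other = pivot.get(low)
            if other is None:
                break
            col ^= other
        if col:
            low = col.bit_length() - 1
            pivot[low] = col
            paired_rank.add(low)
            birth = edge_value_by_rank[low]
            death = float(tvals[ti])
            if death > birth:
                records.append(DiagramRecord(1, birth, death))
    for rank, ei in enumerate(edge_order):
        if positive[ei] and rank not in paired_rank:
            records.append(DiagramRecord(1, float(filtration.edge_values[ei]), inf))
    records.sort(key=lambda r: (r.birth, r.death))
    return PersistenceDiagram(records, filtration_kind=filtration_kind)


@dataclass
class ZigzagIntervals:
    """Interval decomposition (start, end, multiplicity) of a dimension-0
    zigzag module over sequence indices 0 .. 2k-2."""

    intervals: list[tuple[int, int, int]] = field(default_factory=list)
    length: int = 0

    def multiplicity_at(self, index: int) -> int:
        return sum(m for s, e, m in self.intervals if s <= index <= e)


def _components(k: FilteredComplex) -> list[list[int]]:
    """Connected components of a fixed complex, as lists of cell ids."""
    ids = k.vertex_ids if k.vertex_ids is not None else np.arange(k.n_points)
    parent = list(range(k.n_points))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in k.edges:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for v in range(k.n_points):
        groups.setdefault(find(v), []).append(int(ids[v]))
    return [sorted(g) for g in sorted(groups.values())]


def zigzag_ph0(sequence: ZigzagSequence) -> ZigzagIntervals:
    """Interval decomposition of the dimension-0 zigzag persistence module.

    Builds the telescope graph whose nodes are (index, component) and whose
    edges glue each odd-index (intersection) component to its image component
    in the neighbouring snapshots.  The generalized rank over [i, j] is the
    number of telescope components restricted to [i, j] that meet every index;
    multiplicities follow by inclusion-exclusion over segment ranks.
    """
    L = len(sequence.complexes)
    if L == 0:
        return ZigzagIntervals([], 0)
    comps = [_components(k) for k in sequence.complexes]
    # global node ids and per-level membership: cell id -> component index
    node_id: dict[tuple[int, int], int] = {}
    level_of: list[int] = []
    for lev, cs in enumerate(comps):
        for ci in range(len(cs)):
            node_id[(lev, ci)] = len(level_of)
            level_of.append(lev)
    member: list[dict[int, int]] = []
    for cs in comps:
        d: dict[int, int] = {}
        for ci, cells in enumerate(cs):
            for cell in cells:
                d[cell] = ci
        member.append(d)
    # telescope edges: odd component -> containing component on each side
    tele_edges: list[tuple[int, int, int]] = []  # (lower level, node_a, node_b)
    for lev in range(1, L, 2):
        for ci, cells in enumerate(comps[lev]):
            rep = cells[0]
            for nb in (lev - 1, lev + 1):
                if 0 <= nb < L:
                    target = member[nb][rep]
                    a, b = node_id[(lev, ci)], node_id[(nb, target)]
                    tele_edges.append((min(lev, nb), a, b))

    n_nodes = len(level_of)
    level_arr = np.array(level_of, dtype=np.intp)

    def rank(i: int, j: int) -> int:
        """Components of the telescope over levels i..j that meet every level."""
        if i > j:
            return 0
        parent = list(range(n_nodes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for lo, a, b in tele_edges:
            if i <= lo and lo + 1 <= j:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        levels_by_root: dict[int, set[int]] = {}
        for v in range(n_nodes):
            if i <= level_arr[v] <= j:
                levels_by_root.setdefault(find(v), set()).add(int(level_arr[v]))
        needed = j - i + 1
        return sum(1 for s in levels_by_root.values() if len(s) == needed)

    rk = {}
    for i in range(L):
        for j in range(i, L):
            rk[(i, j)] = rank(i, j)

    def rk_at(i: int, j: int) -> int:
        if i < 0 or j >= L or i > j:
            return 0
        return rk[(i, j)]

    intervals = []
    for s in range(L):
        for e in range(s, L):
            mult = rk_at(s, e) - rk_at(s - 1, e) - rk_at(s, e + 1) + rk_at(s - 1, e + 1)
            if mult > 0:
                intervals.append((s, e, mult))
    intervals.sort()
    return ZigzagIntervals(intervals, L)
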