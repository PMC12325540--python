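"""Independent brute-force oracles used to validate the persistence engines.

These deliberately avoid the package's own algorithms: single linkage is
agglomerative over the distance matrix, dimension-1 pairs come from a dense
full-boundary-matrix reduction over all simplices, and zigzag ranks are
computed by explicit GF(2) linear algebra on the limit and colimit of each
segment (with connected components delegated to networkx).
"""

from __future__ import annotations

from math import inf

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform


def single_linkage_heights(points: np.ndarray) -> list[float]:
    """Naive O(n^3) agglomerative single linkage; returns the n-1 merge heights."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dm = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dm[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] |= clusters[b]
        del clusters[b]
    return sorted(heights)


def full_reduction_pairs(filtration) -> dict[int, list[tuple[float, float]]]:
    """Standard persistence pairs by dense reduction of the full boundary matrix.

    Returns {dim: [(birth, death), ...]} including infinite deaths, with
    zero-persistence pairs removed.
    """
    simplices = filtration.simplices()  # already in filtration order
    index = {s.vertices: i for i, s in enumerate(simplices)}
    columns: list[set[int]] = []
    for s in simplices:
        if s.dimension == 0:
            columns.append(set())
        elif s.dimension == 1:
            a, b = s.vertices
            columns.append({index[(a,)], index[(b,)]})
        else:
            a, b, c = s.vertices
            columns.append({index[(a, b)], index[(a, c)], index[(b, c)]})
    low_inverse: dict[int, int] = {}
    lows: list[int | None] = []
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low in low_inverse:
                col ^= columns[low_inverse[low]]
            else:
                break
        columns[j] = col
        if col:
            low = max(col)
            low_inverse[low] = j
            lows.append(low)
        else:
            lows.append(None)
    pairs: dict[int, list[tuple[float, float]]] = {0: [], 1: []}
    paired = set()
    for j, low in enumerate(lows):
        if low is not None:
            paired.add(j)
            paired.add(low)
            dim = simplices[low].dimension
            birth, death = simplices[low].value, simplices[j].value
            if death > birth and dim in pairs:
                pairs[dim].append((birth, death))
    for j, s in enumerate(simplices):
        if j not in paired and lows[j] is None and s.dimension in pairs:
            pairs[s.dimension].append((s.value, inf))
    for dim in pairs:
        pairs[dim].sort()
    return pairs


def _gf2_rank(mat: np.ndarray) -> int:
    m = (np.array(mat, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = m.shape
    for c in range(cols):
        piv = None
        for r in range(rank, rows):
            if m[r, c]:
                piv = r
                break
        if piv is None:
            continue
        m[[rank, piv]] = m[[piv, rank]]
        hit = m[:, c].astype(bool).copy()
        hit[rank] = False
        m[hit] ^= m[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def _gf2_kernel(mat: np.ndarray) -> np.ndarray:
    """Basis (rows) of the null space of ``mat`` over GF(2)."""
    m = (np.array(mat, dtype=np.uint8) % 2).copy()
    rows, cols = m.shape
    pivots = []
    r = 0
    for c in range(cols):
        piv = None
        for rr in range(r, rows):
            if m[rr, c]:
                piv = rr
                break
        if piv is None:
            continue
        m[[r, piv]] = m[[piv, r]]
        hit = m[:, c].astype(bool).copy()
        hit[r] = False
        m[hit] ^= m[r]
        pivots.append(c)
        r += 1
    free = [c for c in range(cols) if c not in pivots]
    basis = []
    for f in free:
        v = np.zeros(cols, dtype=np.uint8)
        v[f] = 1
        for r_idx, c in enumerate(pivots):
            if m[r_idx, f]:
                v[c] = 1
        basis.append(v)
    return np.array(basis, dtype=np.uint8).reshape(len(basis), cols)


def _zigzag_spaces(sequence):
    """Per-index component lists (via networkx) and arrow matrices odd->even."""
    comps = []
    for k in sequence.complexes:
        ids = k.vertex_ids if k.vertex_ids is not None else np.arange(k.n_points)
        g = nx.Graph()
        g.add_nodes_from(int(ids[v]) for v in range(k.n_points))
        g.add_edges_from((int(ids[a]), int(ids[b])) for a, b in k.edges)
        comps.append([sorted(c) for c in sorted(nx.connected_components(g), key=sorted)])
    arrows = {}  # (odd, even) -> matrix (dim_even x dim_odd)
    L = len(sequence.complexes)
    for o in range(1, L, 2):
        for e in (o - 1, o + 1):
            if 0 <= e < L:
                mat = np.zeros((len(comps[e]), len(comps[o])), dtype=np.uint8)
                for ci, cells in enumerate(comps[o]):
                    rep = cells[0]
                    for ei, ecells in enumerate(comps[e]):
                        if rep in ecells:
                            mat[ei, ci] = 1
                            break
                arrows[(o, e)] = mat
    return comps, arrows


def zigzag_generalized_rank(sequence, i: int, j: int) -> int:
    """Rank of the canonical map lim -> colim of the H0 zigzag over [i, j],
    by explicit GF(2) linear algebra."""
    comps, arrows = _zigzag_spaces(sequence)
    dims = [len(c) for c in comps]
    levels = list(range(i, j + 1))
    offset = {}
    total = 0
    for l in levels:
        offset[l] = total
        total += dims[l]
    if total == 0:
        return 0
    cons = []  # constraint rows: A x_o - x_e = 0
    rels = []  # colim relations: iota_o b - iota_e (A b)
    for (o, e), mat in arrows.items():
        if o in offset and e in offset:
            for erow in range(dims[e]):
                row = np.zeros(total, dtype=np.uint8)
                row[offset[e] + erow] = 1
                row[offset[o] : offset[o] + dims[o]] ^= mat[erow]
                cons.append(row)
            for ocol in range(dims[o]):
                row = np.zeros(total, dtype=np.uint8)
                row[offset[o] + ocol] = 1
                row[offset[e] : offset[e] + dims[e]] ^= mat[:, ocol]
                rels.append(row)
    kernel = (
        _gf2_kernel(np.array(cons, dtype=np.uint8))
        if cons
        else np.eye(total, dtype=np.uint8)
    )
    if len(kernel) == 0:
        return 0
    # canonical map lim -> colim: project a limit tuple to the first level,
    # then include into the colimit (independent of the level chosen because
    # the zigzag diagram is connected)
    projected = np.zeros((len(kernel), total), dtype=np.uint8)
    projected[:, offset[i] : offset[i] + dims[i]] = kernel[:, offset[i] : offset[i] + dims[i]]
    rel_mat = np.array(rels, dtype=np.uint8).reshape(len(rels), total)
    rank_rel = _gf2_rank(rel_mat) if len(rels) else 0
    stacked = np.vstack([rel_mat, projected]) if len(rels) else projected
    return _gf2_rank(stacked) - rank_rel


def zigzag_intervals_bruteforce(sequence) -> list[tuple[int, int, int]]:
    """Interval multiplicities from linear-algebra generalized ranks via the
    four-term inclusion-exclusion on segment ranks."""
    L = len(sequence.complexes)
    rk = {}
    for a in range(L):
        for b in range(a, L):
            rk[(a, b)] = zigzag_generalized_rank(sequence, a, b)

    def at(a, b):
        if a < 0 or b >= L or a > b:
            return 0
        return rk[(a, b)]

    out = []
    for s in range(L):
        for e in range(s, L):
            mult = at(s, e) - at(s - 1, e) - at(s, e + 1) + at(s - 1, e + 1)
            if mult > 0:
                out.append((s, e, mult))
    return sorted(out)
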