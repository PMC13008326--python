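"""Independent oracles used by the test suite.

Everything here is deliberately coded separately from the package — set-based
matrix reduction, flood fill via scipy.ndimage, Euler characteristic counts,
closed-form statistics — so agreement with the package is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

import numpy as np
from scipy import ndimage


def flood_fill_components(mask: np.ndarray) -> int:
    """Number of 4-connected components of a boolean raster."""
    _, n = ndimage.label(mask)
    return int(n)


def euler_betti1(mask: np.ndarray) -> int:
    """First Betti number of the occupied cubical complex via Euler's formula.

    beta1 = beta0 - (V - E + F) with vertices = occupied cells, edges between
    4-adjacent occupied cells, faces for fully occupied 2x2 blocks.
    """
    v = int(mask.sum())
    e = int((mask[:-1, :] & mask[1:, :]).sum() + (mask[:, :-1] & mask[:, 1:]).sum())
    f = int((mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]).sum())
    return flood_fill_components(mask) - (v - e + f)


def _complex_cells(mask: np.ndarray, direction: str, cell_size: float):
    """Cells of the cubical complex as (value, dim, frozenset of vertices)."""
    cells: List[Tuple[float, int, frozenset]] = []
    occ = np.argwhere(mask)
    occ_set = {tuple(p) for p in occ}

    def val(p):
        axis = 1 if direction == "vertical" else 0
        return (p[axis] + 0.5) * cell_size

    for p in occ_set:
        cells.append((val(p), 0, frozenset([p])))
    for p in occ_set:
        for d in ((1, 0), (0, 1)):
            q = (p[0] + d[0], p[1] + d[1])
            if q in occ_set:
                cells.append((max(val(p), val(q)), 1, frozenset([p, q])))
    for p in occ_set:
        sq = [p, (p[0] + 1, p[1]), (p[0], p[1] + 1), (p[0] + 1, p[1] + 1)]
        if all(q in occ_set for q in sq):
            cells.append((max(val(q) for q in sq), 2, frozenset(sq)))
    return cells


def ordinary_pairs_oracle(mask: np.ndarray, direction: str,
                          cell_size: float):
    """Ordinary persistence by an independent set-based reduction.

    Returns (finite_pairs, essentials): finite pairs as sorted
    (birth, death, dim) with positive persistence, essentials as sorted
    (birth, dim).
    """
    cells = _complex_cells(mask, direction, cell_size)
    order = sorted(range(len(cells)), key=lambda i: (cells[i][0], cells[i][1]))
    index_of = {cells[i][2]: rank for rank, i in enumerate(order)}

    def boundary(i: int) -> Set[int]:
        _, dim, verts = cells[i]
        if dim == 0:
            return set()
        if dim == 1:
            return {index_of[frozenset([v])] for v in verts}
        vs = sorted(verts)
        edges = []
        for a in vs:
            for b in vs:
                if a < b and abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1:
                    edges.append(frozenset([a, b]))
        return {index_of[e] for e in edges}

    columns: List[Set[int]] = [boundary(i) for i in order]
    low_holder: Dict[int, int] = {}
    pairs: Dict[int, int] = {}
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = max(col)
            if low not in low_holder:
                low_holder[low] = j
                pairs[low] = j
                break
            col ^= columns[low_holder[low]]
        columns[j] = col

    vals = [cells[i][0] for i in order]
    dims = [cells[i][1] for i in order]
    finite = sorted((vals[a], vals[b], dims[a]) for a, b in pairs.items()
                    if vals[a] != vals[b])
    paired = set(pairs) | set(pairs.values())
    essential = sorted((vals[p], dims[p]) for p in range(len(order))
                       if p not in paired)
    return finite, essential


def segment_touches_cell(p0, p1, ix, iy, cs) -> bool:
    """Closed segment-rectangle intersection test (Liang-Barsky, closed)."""
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - ix * cs), (dx, (ix + 1) * cs - x0),
        (-dy, y0 - iy * cs), (dy, (iy + 1) * cs - y0),
    ):
        if p == 0.0:
            if q < 0:
                return False
            continue
        t = q / p
        if p < 0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
        if t0 > t1:
            return False
    return True


def brute_force_supercover(p0, p1, cs, r) -> Set[Tuple[int, int]]:
    return {(i, j) for i in range(r) for j in range(r)
            if segment_touches_cell(p0, p1, i, j, cs)}
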