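"""Extended persistent homology of occupancy grids under sweeping-plane filtrations.

The final-timestep vascular network is a binary raster.  We build a cubical
complex on the occupied cells — one vertex per occupied cell, an edge between
4-adjacent occupied cells, a square for every fully occupied 2x2 block — and
filter it by a coordinate height function ("sweeping plane"): the vertical
filtration assigns each cell its centre ``y`` (sweeping from the bottom edge
towards the tumour at the top), the horizontal filtration its centre ``x``.
Faces take the maximum of their vertex values (lower-star extension), so the
sublevel set at threshold ``k`` is exactly the sub-complex on cells the plane
has passed.

Ordinary persistence of this filtration leaves every connected component and
loop of the full network as an essential class with death ``+inf``.  Extended
persistence removes the infinities by following the ascending (sublevel) pass
with a descending (superlevel, relative-homology) pass; algebraically we
reduce the boundary matrix of the *cone* over the complex, appending a coned
copy of each cell ordered by decreasing minimum vertex value.  Every feature
then receives a finite (birth, death) pair and one of four class labels:

* ``ordinary``   — born and dead in the ascending pass (dim 0: side branches
  growing toward the sweep direction; dim 1 cannot die ascending here);
* ``relative``   — born and dead in the descending pass (dim 1: branches
  pointing away from the sweep origin; reported with birth > death);
* ``extended_plus``  — dim-0 pairs spanning both passes: one per connected
  component, (min, max) extent of the component along the sweep axis;
* ``extended_minus`` — dim-1 pairs spanning both passes: one per independent
  loop, (birth, death) = (top, bottom) extent of the loop along the axis.

All homology is over the field Z/2Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .grid import OccupancyGrid

__all__ = [
    "CLASSES",
    "Filtration",
    "ExtendedDiagram",
    "build_filtration",
    "extended_persistence",
    "ordinary_persistence",
]

CLASSES: Tuple[str, ...] = ("ordinary", "relative", "extended_plus", "extended_minus")


@dataclass
class Filtration:
    """Cubical complex on occupied cells with a lower-star height filtration.

    ``faces`` lists (dim, boundary-face ids); vertices come first, then
    edges, then squares.  ``f_values``/``g_values`` are the max/min vertex
    value of each face (lower-/upper-star extensions).
    """

    direction: str  # "vertical" (height = y) or "horizontal" (height = x)
    vertex_values: np.ndarray  # value of each vertex (occupied-cell centre)
    face_dims: np.ndarray
    face_boundaries: List[Tuple[int, ...]] = field(repr=False)
    f_values: np.ndarray = field(repr=False)
    g_values: np.ndarray = field(repr=False)

    @property
    def n_faces(self) -> int:
        return len(self.face_dims)

    def sublevel_mask(self, k: float) -> np.ndarray:
        """Boolean mask of faces present in the sublevel complex at ``k``."""
        return self.f_values <= k


def build_filtration(grid: OccupancyGrid, direction: str) -> Filtration:
    """Build the sweeping-plane filtration of an occupancy grid.

    Parameters
    ----------
    grid : OccupancyGrid
        Non-empty binary raster.
    direction : {"vertical", "horizontal"}
        ``vertical`` filters by cell-centre ``y`` (sweep from the bottom
        edge, far from the tumour, upwards); ``horizontal`` by ``x``.
    """
    if direction not in ("vertical", "horizontal"):
        raise ValueError("direction must be 'vertical' or 'horizontal'")
    occ = grid.cells
    if not occ.any():
        raise ValueError("cannot filter an empty occupancy grid")
    r = grid.resolution
    cs = grid.cell_size

    vid = -np.ones((r, r), dtype=np.int64)
    ix, iy = np.nonzero(occ)
    n_vert = len(ix)
    vid[ix, iy] = np.arange(n_vert)
    axis_index = iy if direction == "vertical" else ix
    vertex_values = (axis_index + 0.5) * cs

    dims: List[int] = [0] * n_vert
    boundaries: List[Tuple[int, ...]] = [()] * n_vert
    fv: List[float] = list(vertex_values)
    gv: List[float] = list(vertex_values)

    # edges between 4-adjacent occupied cells; remember ids for square faces
    edge_id: Dict[Tuple[int, int], int] = {}
    for dx, dy in ((1, 0), (0, 1)):
        a = occ[: r - dx if dx else r, : r - dy if dy else r]
        b = occ[dx:, dy:] if dx or dy else occ
        ex, ey = np.nonzero(a & b)
        for x0, y0 in zip(ex, ey):
            u = vid[x0, y0]
            v = vid[x0 + dx, y0 + dy]
            edge_id[(int(u), int(v))] = len(dims)
            boundaries.append((int(u), int(v)))
            dims.append(1)
            fv.append(max(vertex_values[u], vertex_values[v]))
            gv.append(min(vertex_values[u], vertex_values[v]))

    # squares for fully occupied 2x2 blocks; boundary = the four edges
    blk = occ[:-1, :-1] & occ[1:, :-1] & occ[:-1, 1:] & occ[1:, 1:]
    sx, sy = np.nonzero(blk)
    for x0, y0 in zip(sx, sy):
        v00 = int(vid[x0, y0])
        v10 = int(vid[x0 + 1, y0])
        v01 = int(vid[x0, y0 + 1])
        v11 = int(vid[x0 + 1, y0 + 1])
        edges = (edge_id[(v00, v10)], edge_id[(v01, v11)],
                 edge_id[(v00, v01)], edge_id[(v10, v11)])
        boundaries.append(edges)
        dims.append(2)
        vals = (vertex_values[v00], vertex_values[v10],
                vertex_values[v01], vertex_values[v11])
        fv.append(max(vals))
        gv.append(min(vals))

    return Filtration(
        direction=direction,
        vertex_values=np.asarray(vertex_values, dtype=float),
        face_dims=np.asarray(dims, dtype=np.int8),
        face_boundaries=boundaries,
        f_values=np.asarray(fv, dtype=float),
        g_values=np.asarray(gv, dtype=float),
    )


@dataclass
class ExtendedDiagram:
    """Extended persistence diagram for one filtration direction.

    Every point has finite birth and death.  ``cls`` entries are drawn from
    :data:`CLASSES`; dims are 0 or 1.
    """

    direction: str
    birth: np.ndarray
    death: np.ndarray
    dim: np.ndarray
    cls: np.ndarray  # array of strings from CLASSES

    def __post_init__(self) -> None:
        self.birth = np.asarray(self.birth, dtype=float)
        self.death = np.asarray(self.death, dtype=float)
        self.dim = np.asarray(self.dim, dtype=np.int8)
        self.cls = np.asarray(self.cls, dtype=object)
        if not (np.all(np.isfinite(self.birth)) and np.all(np.isfinite(self.death))):
            raise ValueError("extended persistence pairs must be finite")
        if self.cls.size and not set(self.cls) <= set(CLASSES):
            raise ValueError("unknown diagram point class")

    def __len__(self) -> int:
        return len(self.birth)

    def select(self, dim: int, cls: str) -> np.ndarray:
        """(n, 2) array of (birth, death) for one (dim, class) stratum."""
        mask = (self.dim == dim) & (self.cls == cls)
        return np.column_stack([self.birth[mask], self.death[mask]])

    @property
    def n_components(self) -> int:
        """Betti-0 of the full complex (= extended-plus dim-0 count)."""
        return int(np.sum((self.dim == 0) & (self.cls == "extended_plus")))

    @property
    def n_loops(self) -> int:
        """Betti-1 of the full complex (= extended-minus dim-1 count)."""
        return int(np.sum((self.dim == 1) & (self.cls == "extended_minus")))


def _reduce(columns: List[int]) -> Dict[int, int]:
    """Standard persistence matrix reduction over Z/2.

    Columns are bitmasks of row indices in filtration order.  Returns the
    pairing ``{birth_index: death_index}``.
    """
    low_to_col: Dict[int, int] = {}
    pairs: Dict[int, int] = {}
    for j, col in enumerate(columns):
        while col:
            low = col.bit_length() - 1
            holder = low_to_col.get(low)
            if holder is None:
                low_to_col[low] = j
                pairs[low] = j
                columns[j] = col
                break
            col ^= columns[holder]
        else:
            columns[j] = 0
    return pairs


def extended_persistence(filtration: Filtration) -> ExtendedDiagram:
    """Compute the extended persistence diagram of a lower-star filtration.

    Reduces the boundary matrix of the cone: ascending cells ordered by
    (max vertex value, dim), then a coned copy of each cell ordered by
    (decreasing min vertex value, dim).  Pairs internal to the ascending pass
    are ordinary, pairs internal to the descending pass are relative (feature
    dimension = cell dimension + 1), and ascending-birth/descending-death
    pairs are the extended classes.  Zero-persistence ordinary and relative
    pairs are discarded; only dimensions 0 and 1 are reported.
    """
    n = filtration.n_faces
    f = filtration.f_values
    g = filtration.g_values
    dims = filtration.face_dims

    asc = sorted(range(n), key=lambda i: (f[i], dims[i], i))
    desc = sorted(range(n), key=lambda i: (-g[i], dims[i], i))
    pos_asc = np.empty(n, dtype=np.int64)
    pos_asc[asc] = np.arange(n)
    pos_desc = np.empty(n, dtype=np.int64)
    pos_desc[desc] = n + np.arange(n)

    columns: List[int] = []
    for i in asc:
        col = 0
        for b in filtration.face_boundaries[i]:
            col |= 1 << int(pos_asc[b])
        columns.append(col)
    for i in desc:
        col = 1 << int(pos_asc[i])
        for b in filtration.face_boundaries[i]:
            col |= 1 << int(pos_desc[b])
        columns.append(col)

    pairs = _reduce(columns)
    order = asc + desc  # global position -> face id

    births: List[float] = []
    deaths: List[float] = []
    pdim: List[int] = []
    pcls: List[str] = []
    for lo, hi in pairs.items():
        face_lo, face_hi = order[lo], order[hi]
        if lo < n and hi < n:  # ordinary
            b, d = f[face_lo], f[face_hi]
            k = int(dims[face_lo])
            c = "ordinary"
            if b == d:
                continue
        elif lo < n <= hi:  # extended
            b, d = f[face_lo], g[face_hi]
            k = int(dims[face_lo])
            c = "extended_plus" if k == 0 else "extended_minus"
        else:  # relative
            b, d = g[face_lo], g[face_hi]
            k = int(dims[face_lo]) + 1
            c = "relative"
            if b == d:
                continue
        if k > 1:
            continue
        births.append(float(b))
        deaths.append(float(d))
        pdim.append(k)
        pcls.append(c)

    return ExtendedDiagram(
        direction=filtration.direction,
        birth=np.asarray(births, dtype=float),
        death=np.asarray(deaths, dtype=float),
        dim=np.asarray(pdim, dtype=np.int8),
        cls=np.asarray(pcls, dtype=object),
    )


def ordinary_persistence(filtration: Filtration) -> List[Tuple[float, float, int]]:
    """Ordinary (non-extended) persistence of the ascending filtration.

    Returns ``(birth, death, dim)`` triples; essential classes carry
    ``death = +inf``.  Zero-persistence pairs are discarded.  Used for
    side-by-side comparison with the extended diagram (the finite pairs of
    ordinary persistence coincide with the ``ordinary`` class of
    :func:`extended_persistence`).
    """
    n = filtration.n_faces
    f = filtration.f_values
    dims = filtration.face_dims
    asc = sorted(range(n), key=lambda i: (f[i], dims[i], i))
    pos = np.empty(n, dtype=np.int64)
    pos[asc] = np.arange(n)
    columns: List[int] = []
    for i in asc:
        col = 0
        for b in filtration.face_boundaries[i]:
            col |= 1 << int(pos[b])
        columns.append(col)
    pairs = _reduce(columns)
    paired = set(pairs) | set(pairs.values())
    out: List[Tuple[float, float, int]] = []
    for lo, hi in pairs.items():
        b, d = f[asc[lo]], f[asc[hi]]
        if b != d:
            out.append((float(b), float(d), int(dims[asc[lo]])))
    for p in range(n):
        if p not in paired and columns[p] == 0:
            out.append((float(f[asc[p]]), np.inf, int(dims[asc[p]])))
    return sorted(out, key=lambda t: (t[2], t[0], t[1]))
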