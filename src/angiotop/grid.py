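"""Occupancy grids: the shared raster substrate for all summary statistics.

The three simulators produce trail geometry in two forms — occupied lattice
sites (AC) and per-tip continuous polylines (SL, PS).  Both are projected onto
a regular ``R x R`` grid of square cells covering ``[0, L]^2``; polyline
segments are rasterized with a *supercover* line draw, so consecutive trail
points occupy a 4-connected chain of cells and every cell whose closed square
the segment touches is marked.  The default resolution equals the AC lattice
resolution, which makes AC rasterization the identity map from lattice sites
to cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Set, Tuple

import numpy as np

__all__ = ["OccupancyGrid", "rasterize", "supercover_cells"]


@dataclass
class OccupancyGrid:
    """Binary raster of the domain.

    ``cells`` is indexed ``[ix, iy]`` with ``iy`` increasing towards the
    tumour; cell ``(ix, iy)`` covers
    ``[ix*cs, (ix+1)*cs] x [iy*cs, (iy+1)*cs]`` with ``cs = L / resolution``.
    """

    resolution: int
    side_length: float
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.resolution < 8:
            raise ValueError("grid resolution must be >= 8")
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.shape != (self.resolution, self.resolution):
            raise ValueError("cells must be a resolution x resolution array")

    @property
    def cell_size(self) -> float:
        return self.side_length / self.resolution

    @property
    def n_occupied(self) -> int:
        return int(self.cells.sum())

    def occupied_centers(self) -> np.ndarray:
        """(n, 2) array of centres of occupied cells, in domain coordinates."""
        ix, iy = np.nonzero(self.cells)
        cs = self.cell_size
        return np.column_stack([(ix + 0.5) * cs, (iy + 0.5) * cs])

    def mirror_x(self) -> "OccupancyGrid":
        """Left-right mirrored copy (used by symmetry checks)."""
        return OccupancyGrid(self.resolution, self.side_length,
                             self.cells[::-1, :].copy())


def _cell_of(x: float, cs: float, r: int) -> int:
    return int(np.clip(np.floor(x / cs), 0, r - 1))


def supercover_cells(
    p0: Tuple[float, float],
    p1: Tuple[float, float],
    cell_size: float,
    resolution: int,
) -> Set[Tuple[int, int]]:
    """Cells whose closed square a segment touches (supercover rasterization).

    Crossing parameters along the segment are enumerated analytically; every
    interval between consecutive crossings contributes the cell containing its
    midpoint, and an exact corner crossing contributes all four incident
    cells.  The result is a 4-connected chain from the cell of ``p0`` to the
    cell of ``p1``.
    """
    cs, r = cell_size, resolution
    (x0, y0), (x1, y1) = p0, p1
    dx, dy = x1 - x0, y1 - y0
    cells: Set[Tuple[int, int]] = set()

    def clip(i: int) -> int:
        return int(np.clip(i, 0, r - 1))

    tx: Set[float] = set()
    ty: Set[float] = set()
    if dx != 0.0:
        lo, hi = sorted((x0, x1))
        for i in range(int(np.ceil(lo / cs)), int(np.floor(hi / cs)) + 1):
            t = (i * cs - x0) / dx
            if 0.0 < t < 1.0:
                tx.add(t)
    if dy != 0.0:
        lo, hi = sorted((y0, y1))
        for j in range(int(np.ceil(lo / cs)), int(np.floor(hi / cs)) + 1):
            t = (j * cs - y0) / dy
            if 0.0 < t < 1.0:
                ty.add(t)

    ts = sorted({0.0, 1.0} | tx | ty)
    for a, b in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (a + b)
        cells.add((_cell_of(x0 + tm * dx, cs, r), _cell_of(y0 + tm * dy, cs, r)))
    for t in tx & ty:  # exact corner crossing: all four incident cells
        cx = round((x0 + t * dx) / cs)
        cy = round((y0 + t * dy) / cs)
        for ox in (-1, 0):
            for oy in (-1, 0):
                cells.add((clip(cx + ox), clip(cy + oy)))
    cells.add((_cell_of(x0, cs, r), _cell_of(y0, cs, r)))
    cells.add((_cell_of(x1, cs, r), _cell_of(y1, cs, r)))
    return cells


def rasterize(result, resolution: int | None = None) -> OccupancyGrid:
    """Project a simulation's trail geometry onto an occupancy grid.

    Parameters
    ----------
    result : SimulationResult
        Output of :func:`angiotop.simulators.simulate`.  Lattice trail sites
        (AC) map one-to-one onto cells when ``resolution`` equals the lattice
        resolution; polylines (SL, PS) are supercover-rasterized segment by
        segment.
    resolution : int, optional
        Grid resolution; defaults to the simulation's lattice resolution.

    Raises
    ------
    ValueError
        If the trail is empty or the resolution is below 8.
    """
    config = result.config
    r = int(resolution) if resolution is not None else config.lattice_resolution
    if r < 8:
        raise ValueError("grid resolution must be >= 8")
    L = config.side_length
    cells = np.zeros((r, r), dtype=bool)
    cs = L / r

    trail_cells = getattr(result, "trail_cells", None)
    if (result.trail_sites is None and trail_cells is not None
            and r == config.lattice_resolution):
        # native resolution: the simulator already rasterized the trail as it
        # was laid, cell by cell
        if len(trail_cells) == 0:
            raise ValueError("cannot rasterize an empty trail")
        cells[trail_cells[:, 0], trail_cells[:, 1]] = True
        return OccupancyGrid(resolution=r, side_length=L, cells=cells)

    if result.trail_sites is not None:
        sites = np.asarray(result.trail_sites)
        if sites.size == 0:
            raise ValueError("cannot rasterize an empty trail")
        h = config.h
        ix = np.clip(np.floor(sites[:, 0] * h / cs).astype(int), 0, r - 1)
        iy = np.clip(np.floor(sites[:, 1] * h / cs).astype(int), 0, r - 1)
        cells[ix, iy] = True
    else:
        polylines: Iterable[np.ndarray] = result.polylines
        any_pts = False
        for line in polylines:
            pts = np.asarray(line, dtype=float)
            if len(pts) == 0:
                continue
            any_pts = True
            if len(pts) == 1:
                cells[_cell_of(pts[0, 0], cs, r), _cell_of(pts[0, 1], cs, r)] = True
                continue
            for a, b in zip(pts[:-1], pts[1:]):
                for cx, cy in supercover_cells(tuple(a), tuple(b), cs, r):
                    cells[cx, cy] = True
        if not any_pts:
            raise ValueError("cannot rasterize an empty trail")

    return OccupancyGrid(resolution=r, side_length=L, cells=cells)
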