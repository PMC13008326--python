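"""Extended persistence: oracle agreement, worked examples, invariants."""

import numpy as np
import pytest

from angiotop import (ExtendedDiagram, OccupancyGrid, build_filtration,
                      extended_persistence, ordinary_persistence)

from oracles import (euler_betti1, flood_fill_components,
                     ordinary_pairs_oracle)
from conftest import random_grid, y_with_loop_grid


def grid_from(occ):
    occ = np.asarray(occ, dtype=bool)
    return OccupancyGrid(occ.shape[0], 1.0, occ)


def ring_grid(size=8, lo=2, hi=5):
    occ = np.zeros((size, size), dtype=bool)
    occ[lo:hi, lo:hi] = True
    occ[lo + 1:hi - 1, lo + 1:hi - 1] = False
    return grid_from(occ)


class TestFiltration:
    def test_single_cell_single_vertex(self):
        occ = np.zeros((8, 8), dtype=bool)
        occ[3, 5] = True
        f = build_filtration(grid_from(occ), "vertical")
        assert f.n_faces == 1
        assert f.vertex_values[0] == pytest.approx((5 + 0.5) / 8)

    def test_full_column_connected_at_every_level(self):
        occ = np.zeros((8, 8), dtype=bool)
        occ[4, :] = True
        g = grid_from(occ)
        f = build_filtration(g, "vertical")
        for k in np.linspace(0.1, 1.0, 5):
            mask = f.sublevel_mask(k)
            # restrict the raster to cells below the sweep and flood fill
            sub = g.cells & (np.add.outer(np.zeros(8), np.arange(8) + 0.5) / 8 <= k)
            if sub.any():
                assert flood_fill_components(sub) == 1

    def test_sublevel_counts_match_flood_fill(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            g = random_grid(rng, 8)
            f = build_filtration(g, "vertical")
            centers_y = (np.arange(8) + 0.5) / 8
            for k in np.linspace(0.15, 1.0, 5):
                sub = g.cells & (centers_y[None, :] <= k)
                if not sub.any():
                    continue
                # components of the sublevel complex = flood fill of raster
                vmask = f.sublevel_mask(k) & (f.face_dims == 0)
                assert vmask.sum() == sub.sum()
                assert flood_fill_components(sub) == _betti0_of_sublevel(f, k)

    def test_nestedness(self):
        rng = np.random.default_rng(3)
        g = random_grid(rng, 10)
        f = build_filtration(g, "horizontal")
        m1, m2 = f.sublevel_mask(0.3), f.sublevel_mask(0.7)
        assert np.all(m2 | ~m1)  # m1 subset of m2


def _betti0_of_sublevel(f, k):
    """Component count of the sublevel complex via union-find on edges."""
    present = np.nonzero(f.sublevel_mask(k))[0]
    verts = [i for i in present if f.face_dims[i] == 0]
    parent = {v: v for v in verts}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in present:
        if f.face_dims[i] == 1:
            u, v = f.face_boundaries[i]
            parent[find(u)] = find(v)
    return len({find(v) for v in verts})


class TestExtendedPersistence:
    def test_ring_extent(self):
        g = ring_grid()
        d = extended_persistence(build_filtration(g, "vertical"))
        a, b = (2 + 0.5) / 8, (4 + 0.5) / 8
        assert d.n_components == 1 and d.n_loops == 1
        ext0 = d.select(0, "extended_plus")
        ext1 = d.select(1, "extended_minus")
        assert ext0[0] == pytest.approx([a, b])
        assert ext1[0] == pytest.approx([b, a])
        assert len(d.select(0, "ordinary")) == 0
        assert len(d.select(1, "relative")) == 0

    def test_two_disjoint_bars(self):
        occ = np.zeros((8, 8), dtype=bool)
        occ[1, 2:6] = True
        occ[6, 1:5] = True
        d = extended_persistence(build_filtration(grid_from(occ), "vertical"))
        assert d.n_components == 2
        assert d.n_loops == 0

    def test_worked_vessel_example(self):
        """Stem + loop + branches: ordinary persistence leaves the component
        and the loop essential; extended persistence makes both finite at the
        structure's extents and keeps the finite ordinary pair."""
        g, cs = y_with_loop_grid()
        filt = build_filtration(g, "vertical")
        ordinary = ordinary_persistence(filt)
        essentials = [(b, dim) for b, dth, dim in ordinary if np.isinf(dth)]
        finite = [(b, dth, dim) for b, dth, dim in ordinary if np.isfinite(dth)]
        c = lambda row: (row + 0.5) * cs
        # one essential component born at the bottom, one essential loop born
        # where its top row closes
        assert sorted(essentials) == [
            pytest.approx((c(0), 0)), pytest.approx((c(8), 1))]
        # the hanging lower branch is the only finite ordinary pair
        assert finite == [pytest.approx((c(1), c(2), 0))]

        d = extended_persistence(filt)
        assert np.all(np.isfinite(d.birth)) and np.all(np.isfinite(d.death))
        assert d.select(0, "extended_plus")[0] == pytest.approx([c(0), c(12)])
        assert d.select(1, "extended_minus")[0] == pytest.approx([c(8), c(4)])
        assert d.select(0, "ordinary")[0] == pytest.approx([c(1), c(2)])
        # the small upper branch appears only in the relative (descending)
        # part: born at its tip, merging at the loop top
        assert d.select(1, "relative")[0] == pytest.approx([c(10), c(8)])

    @pytest.mark.parametrize("direction", ["vertical", "horizontal"])
    def test_betti_counts_match_oracles_on_random_grids(self, direction):
        rng = np.random.default_rng(7)
        for _ in range(100):
            g = random_grid(rng, int(rng.integers(8, 13)))
            d = extended_persistence(build_filtration(g, direction))
            assert d.n_components == flood_fill_components(g.cells)
            assert d.n_loops == euler_betti1(g.cells)

    @pytest.mark.parametrize("direction", ["vertical", "horizontal"])
    def test_ordinary_class_matches_independent_reduction(self, direction):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g = random_grid(rng, int(rng.integers(8, 13)))
            filt = build_filtration(g, direction)
            finite, essential = ordinary_pairs_oracle(
                g.cells, direction, g.cell_size)
            ours = sorted((b, dth, int(k)) for b, dth, k
                          in ordinary_persistence(filt) if np.isfinite(dth))
            assert ours == pytest.approx(finite)
            d = extended_persistence(filt)
            ord_pts = sorted(
                [(b, dth, int(k)) for b, dth, k, c in
                 zip(d.birth, d.death, d.dim, d.cls) if c == "ordinary"])
            assert ord_pts == pytest.approx(finite)
            # essential classes of ordinary PH = extended classes of EPH
            ess_dims = sorted(dim for _, dim in essential)
            ext_dims = sorted([0] * d.n_components + [1] * d.n_loops)
            assert ess_dims == ext_dims

    def test_all_diagrams_finite(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            g = random_grid(rng, 10, p=float(rng.uniform(0.2, 0.8)))
            for direction in ("vertical", "horizontal"):
                d = extended_persistence(build_filtration(g, direction))
                assert np.all(np.isfinite(d.birth))
                assert np.all(np.isfinite(d.death))

    def test_diagram_rejects_infinite_points(self):
        with pytest.raises(ValueError):
            ExtendedDiagram("vertical", [0.0], [np.inf], [0], ["ordinary"])
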