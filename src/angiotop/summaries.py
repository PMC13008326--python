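"""Summary statistics of one simulation: spatial averages + topology.

The feature vector of a simulation concatenates

* 18 *spatially-averaged* statistics — mean, standard deviation, minimum,
  maximum, range and the 10th/25th/75th/90th percentiles of the x and the y
  coordinates of occupied grid-cell centres (columns ``sx_*`` / ``sy_*``);
* the *topological* block — persistence images and persistence statistics of
  the extended persistence diagrams under the vertical and horizontal
  sweeping-plane filtrations (columns ``t_*``; see
  :mod:`angiotop.vectorize`).

Statistics are computed over the deduplicated set of occupied cells, so
on-lattice and off-lattice models feed identical downstream machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

import numpy as np
import pandas as pd

from .grid import OccupancyGrid, rasterize
from .topology import build_filtration, extended_persistence
from .vectorize import PersistenceImageConfig, vectorize_diagrams

__all__ = [
    "FeatureConfig",
    "spatial_statistics",
    "topo_features",
    "featurize",
    "featurize_many",
    "feature_type",
    "feature_direction",
]

_SPATIAL_STATS = ("mean", "std", "min", "max", "range", "p10", "p25", "p75", "p90")


@dataclass(frozen=True)
class FeatureConfig:
    """Settings of the featurization stage, fixed pipeline-wide."""

    resolution: int | None = None  # raster resolution; None -> lattice resolution
    image_resolution: int = 10
    image_bandwidth: float | None = None  # None -> extent / 20
    image_weight_power: float = 1.0

    def image_config(self, side_length: float) -> PersistenceImageConfig:
        return PersistenceImageConfig(
            resolution=self.image_resolution,
            extent=side_length,
            bandwidth=self.image_bandwidth,
            weight_power=self.image_weight_power,
        )


def spatial_statistics(grid: OccupancyGrid) -> pd.Series:
    """The 18 spatially-averaged statistics of an occupancy grid.

    Percentiles use linear interpolation between order statistics; the
    standard deviation is the population value.  Raises on an empty grid.
    """
    centers = grid.occupied_centers()
    if len(centers) == 0:
        raise ValueError("occupancy grid is empty")
    values: List[float] = []
    names: List[str] = []
    for axis, tag in ((0, "sx"), (1, "sy")):
        v = centers[:, axis]
        q10, q25, q75, q90 = np.percentile(v, [10, 25, 75, 90])
        stats = (v.mean(), v.std(), v.min(), v.max(), v.max() - v.min(),
                 q10, q25, q75, q90)
        values.extend(stats)
        names.extend(f"{tag}_{s}" for s in _SPATIAL_STATS)
    return pd.Series(values, index=names)


def topo_features(grid: OccupancyGrid, config: FeatureConfig = FeatureConfig()
                  ) -> pd.Series:
    """Topological feature vector of an occupancy grid (both filtrations)."""
    diagrams = {
        direction: extended_persistence(build_filtration(grid, direction))
        for direction in ("vertical", "horizontal")
    }
    return vectorize_diagrams(diagrams, config.image_config(grid.side_length))


def featurize(result, config: FeatureConfig = FeatureConfig()) -> pd.Series:
    """Full feature vector (spatial + topological) of one simulation."""
    grid = rasterize(result, config.resolution)
    return pd.concat([spatial_statistics(grid), topo_features(grid, config)])


def featurize_many(results: Iterable, config: FeatureConfig = FeatureConfig()
                   ) -> pd.DataFrame:
    """Feature table with one row per simulation."""
    return pd.DataFrame([featurize(r, config) for r in results])


def feature_type(name: str) -> str:
    """'spatial' or 'topological', from the column name."""
    if name.startswith(("sx_", "sy_")):
        return "spatial"
    if name.startswith("t_"):
        return "topological"
    raise ValueError(f"not a feature column: {name!r}")


def feature_direction(name: str) -> str:
    """Coordinate direction ('x' or 'y') a feature is computed in.

    Spatial ``sx_*``/``sy_*`` statistics summarize x/y coordinates; the
    vertical sweeping-plane filtration (``t_v_*``) measures structure along
    y, the horizontal one (``t_h_*``) along x.
    """
    if name.startswith("sx_"):
        return "x"
    if name.startswith("sy_"):
        return "y"
    if name.startswith("t_v_"):
        return "y"
    if name.startswith("t_h_"):
        return "x"
    raise ValueError(f"not a feature column: {name!r}")
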