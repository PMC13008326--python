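"""Vectorization of extended persistence diagrams.

Each extended diagram is split into four strata — (dim 0, ordinary),
(dim 1, relative), (dim 0, extended_plus), (dim 1, extended_minus) — and
every stratum is turned into fixed-length numbers in two ways:

* **persistence image**: each point contributes a Gaussian bump at
  ``(birth, persistence)`` with ``persistence = |death - birth|``, weighted
  linearly by persistence (weight zero on the diagonal), evaluated on a fixed
  pixel grid covering ``[0, L] x [0, L]``;
* **persistence statistics**: mean, standard deviation, median, interquartile
  range and the 10th/25th/75th/90th percentiles of the births, deaths,
  midpoints ``(b + d) / 2`` and lifespans ``|d - b|``, plus the persistent
  entropy of the normalized lifespans.

Empty strata map to all-zero blocks so every simulation yields a vector of
identical length and column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .topology import ExtendedDiagram

__all__ = [
    "STRATA",
    "PersistenceImageConfig",
    "persistence_image",
    "persistence_statistics",
    "stat_names",
    "image_names",
]

#: (dim, class, short label) strata in fixed order
STRATA: Tuple[Tuple[int, str, str], ...] = (
    (0, "ordinary", "ord0"),
    (1, "relative", "rel1"),
    (0, "extended_plus", "ext0"),
    (1, "extended_minus", "ext1"),
)

_SAMPLES = ("birth", "death", "mid", "life")
_STATS = ("mean", "std", "median", "iqr", "p10", "p25", "p75", "p90")


@dataclass(frozen=True)
class PersistenceImageConfig:
    """Persistence-image settings, fixed pipeline-wide.

    ``extent`` is the side of the (birth, persistence) box; bandwidth
    defaults to ``extent / 20``; the point weight is
    ``(persistence / extent) ** weight_power`` (linear by default, zero at
    zero persistence).
    """

    resolution: int = 10
    extent: float = 1.0
    bandwidth: float | None = None
    weight_power: float = 1.0

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("image resolution must be >= 1")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.extent <= 0:
            raise ValueError("extent must be positive")

    @property
    def sigma(self) -> float:
        return self.bandwidth if self.bandwidth is not None else self.extent / 20.0

    def pixel_centers(self) -> np.ndarray:
        step = self.extent / self.resolution
        return (np.arange(self.resolution) + 0.5) * step


def persistence_image(points: np.ndarray,
                      config: PersistenceImageConfig) -> np.ndarray:
    """Persistence image of one diagram stratum, flattened row-major.

    ``points`` is an (n, 2) array of (birth, death); an empty stratum gives
    the all-zero vector of full length.
    """
    res = config.resolution
    out = np.zeros((res, res), dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return out.ravel()
    b = pts[:, 0]
    p = np.abs(pts[:, 1] - pts[:, 0])
    w = (p / config.extent) ** config.weight_power
    centers = config.pixel_centers()
    sig2 = 2.0 * config.sigma ** 2
    gx = np.exp(-((centers[None, :] - b[:, None]) ** 2) / sig2)  # (n, res)
    gy = np.exp(-((centers[None, :] - p[:, None]) ** 2) / sig2)
    out = np.einsum("n,nx,ny->xy", w, gx, gy)
    return out.ravel()


def persistence_statistics(points: np.ndarray) -> np.ndarray:
    """Summary statistics of one diagram stratum (33 values).

    Order: for each of births, deaths, midpoints, lifespans — mean, std,
    median, IQR, p10, p25, p75, p90 (linear percentile interpolation) — then
    the persistent entropy of normalized lifespans.  Empty strata give the
    all-zero block.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    out = np.zeros(len(_SAMPLES) * len(_STATS) + 1)
    if len(pts) == 0:
        return out
    b, d = pts[:, 0], pts[:, 1]
    life = np.abs(d - b)
    samples = (b, d, 0.5 * (b + d), life)
    k = 0
    for s in samples:
        q10, q25, q50, q75, q90 = np.percentile(s, [10, 25, 50, 75, 90])
        out[k:k + 8] = (s.mean(), s.std(), q50, q75 - q25, q10, q25, q75, q90)
        k += 8
    total = life.sum()
    if total > 0:
        frac = life[life > 0] / total
        out[k] = float(-(frac * np.log(frac)).sum())
    return out


def stat_names(prefix: str) -> List[str]:
    names = [f"{prefix}_{s}_{t}" for s in _SAMPLES for t in _STATS]
    names.append(f"{prefix}_entropy")
    return names


def image_names(prefix: str, resolution: int) -> List[str]:
    return [f"{prefix}_im{k:02d}" for k in range(resolution * resolution)]


def vectorize_diagrams(diagrams: Dict[str, ExtendedDiagram],
                       config: PersistenceImageConfig) -> pd.Series:
    """Topological feature vector: images for every stratum, then statistics.

    ``diagrams`` maps direction ("vertical"/"horizontal") to its extended
    diagram.  Column order is fixed: all persistence images (direction v, h;
    strata in :data:`STRATA` order), then all statistics blocks in the same
    order.  Names carry a ``t_`` prefix, e.g. ``t_v_ext1_im03``,
    ``t_h_ord0_life_mean``.
    """
    dir_tags = (("vertical", "v"), ("horizontal", "h"))
    values: List[np.ndarray] = []
    names: List[str] = []
    for direction, tag in dir_tags:
        dg = diagrams[direction]
        for dim, cls, label in STRATA:
            pts = dg.select(dim, cls)
            values.append(persistence_image(pts, config))
            names.extend(image_names(f"t_{tag}_{label}", config.resolution))
    for direction, tag in dir_tags:
        dg = diagrams[direction]
        for dim, cls, label in STRATA:
            pts = dg.select(dim, cls)
            values.append(persistence_statistics(pts))
            names.extend(stat_names(f"t_{tag}_{label}"))
    return pd.Series(np.concatenate(values), index=names)
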