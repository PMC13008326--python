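"""Simulation domain and environment fields.

All three angiogenesis models run in a square domain ``[0, L] x [0, L]`` with a
tumour along the top edge (``y = L``).  VEGF (vascular endothelial growth
factor) secreted by the tumour forms a concentration field ``c(x, y)`` that
increases from bottom to top and guides endothelial tip cells upwards.  The
Anderson--Chaplain lattice model additionally reads a fibronectin field
``f(x, y)`` (a bound substrate sensed by haptotaxis).

Both fields live on the shared lattice of ``resolution x resolution`` nodes
with spacing ``h = L / (resolution - 1)``; off-lattice models interpolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DomainConfig", "EnvironmentFields", "make_environment"]


@dataclass(frozen=True)
class DomainConfig:
    """Geometry and time discretization shared by the simulators.

    Parameters
    ----------
    side_length : float
        Domain side ``L`` (dimensionless).
    lattice_resolution : int
        Number of lattice nodes per side (>= 8).  Node spacing is
        ``h = L / (lattice_resolution - 1)``.  The same resolution is the
        default rasterization grid for the summary statistics.
    n_initial_tips : int
        Number of tip cells seeded evenly along the bottom edge (>= 2).
    n_timesteps : int
        Number of simulation steps.
    dt : float
        Time step in model time units.
    """

    side_length: float = 1.0
    lattice_resolution: int = 33
    n_initial_tips: int = 5
    n_timesteps: int = 200
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.lattice_resolution < 8:
            raise ValueError("lattice_resolution must be >= 8")
        if self.n_initial_tips < 2:
            raise ValueError("need at least 2 initial tip cells")
        if self.n_timesteps < 1:
            raise ValueError("n_timesteps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def h(self) -> float:
        """Lattice spacing."""
        return self.side_length / (self.lattice_resolution - 1)

    def node_coords(self) -> np.ndarray:
        """1-D array of node coordinates along one axis."""
        return np.linspace(0.0, self.side_length, self.lattice_resolution)


@dataclass
class EnvironmentFields:
    """VEGF and fibronectin fields sampled on the lattice.

    Arrays are indexed ``[ix, iy]`` with ``iy`` increasing towards the tumour
    at the top.  Values are nondimensional concentrations in ``[0, 1]``;
    ``vegf`` is non-decreasing in ``y`` at every ``x`` initially.
    """

    config: DomainConfig
    vegf: np.ndarray = field(repr=False)
    fibronectin: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        r = self.config.lattice_resolution
        for name, arr in (("vegf", self.vegf), ("fibronectin", self.fibronectin)):
            if arr.shape != (r, r):
                raise ValueError(f"{name} must have shape ({r}, {r})")
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} values must lie in [0, 1]")

    def vegf_at(self, x: float, y: float) -> float:
        """Bilinear interpolation of the VEGF field at a continuous point."""
        return float(self.vegf_at_many(np.array([[x, y]]))[0])

    def vegf_at_many(self, points: np.ndarray) -> np.ndarray:
        """Vectorized bilinear interpolation of VEGF at ``(n, 2)`` points."""
        return _bilinear_many(self.vegf, self.config, points)

    def vegf_gradient(self, x: float, y: float) -> np.ndarray:
        """Interpolated VEGF gradient at a continuous point."""
        return self.vegf_gradient_many(np.array([[x, y]]))[0]

    def vegf_gradient_many(self, points: np.ndarray) -> np.ndarray:
        """Vectorized VEGF gradient at ``(n, 2)`` points.

        Node gradients are central differences (one-sided at the edges),
        interpolated bilinearly between nodes.
        """
        if not hasattr(self, "_grad"):
            h = self.config.h
            gx, gy = np.gradient(self.vegf, h, h)
            object.__setattr__(self, "_grad", (gx, gy))
        gx, gy = self._grad
        return np.column_stack([
            _bilinear_many(gx, self.config, points),
            _bilinear_many(gy, self.config, points),
        ])


def _bilinear_many(arr: np.ndarray, config: DomainConfig,
                   points: np.ndarray) -> np.ndarray:
    h = config.h
    r = config.lattice_resolution
    pts = np.asarray(points, dtype=float)
    fx = np.clip(pts[:, 0] / h, 0, r - 1)
    fy = np.clip(pts[:, 1] / h, 0, r - 1)
    i0 = np.minimum(fx.astype(int), r - 2)
    j0 = np.minimum(fy.astype(int), r - 2)
    tx, ty = fx - i0, fy - j0
    return (arr[i0, j0] * (1 - tx) * (1 - ty)
            + arr[i0 + 1, j0] * tx * (1 - ty)
            + arr[i0, j0 + 1] * (1 - tx) * ty
            + arr[i0 + 1, j0 + 1] * tx * ty)


def make_environment(
    config: DomainConfig,
    profile: str = "linear",
    *,
    decay: float = 3.0,
    fibronectin_slope: float = 0.4,
) -> EnvironmentFields:
    """Construct initial VEGF and fibronectin fields.

    Parameters
    ----------
    config : DomainConfig
    profile : {"linear", "exponential"}
        Initial VEGF profile.  ``linear``: ``c(x, y) = y / L``.
        ``exponential``: ``c(x, y) = exp(-decay * (L - y) / L)`` — steep
        accumulation of VEGF near the tumour.
    decay : float
        Decay constant ``k`` of the exponential profile.
    fibronectin_slope : float
        Initial fibronectin decreases linearly from 1 at the bottom to
        ``1 - fibronectin_slope`` at the top (pre-existing matrix is densest
        away from the tumour).

    Returns
    -------
    EnvironmentFields
        VEGF maximal along ``y = L``; both fields in ``[0, 1]``.
    """
    coords = config.node_coords()
    y = np.broadcast_to(coords[None, :], (config.lattice_resolution,) * 2)
    if profile == "linear":
        vegf = y / config.side_length
    elif profile == "exponential":
        vegf = np.exp(-decay * (config.side_length - y) / config.side_length)
    else:
        raise ValueError(f"unknown VEGF profile {profile!r}")
    if not 0 <= fibronectin_slope <= 1:
        raise ValueError("fibronectin_slope must lie in [0, 1]")
    fibr = 1.0 - fibronectin_slope * y / config.side_length
    return EnvironmentFields(config=config, vegf=np.ascontiguousarray(vegf),
                             fibronectin=np.ascontiguousarray(fibr))
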