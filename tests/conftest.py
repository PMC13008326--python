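import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from angiotop import OccupancyGrid, PipelineConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_grid(rng: np.random.Generator, size: int = 10,
                p: float = 0.5) -> OccupancyGrid:
    """Random occupancy raster with at least one occupied cell."""
    occ = rng.random((size, size)) < p
    if not occ.any():
        occ[size // 2, size // 2] = True
    return OccupancyGrid(max(size, 8), 1.0, _pad(occ, max(size, 8)))


def _pad(occ: np.ndarray, size: int) -> np.ndarray:
    out = np.zeros((size, size), dtype=bool)
    out[: occ.shape[0], : occ.shape[1]] = occ
    return out


def y_with_loop_grid() -> tuple[OccupancyGrid, float]:
    """A simple vessel: stem, one loop, two upper branches and a hanging
    lower branch, on a 16x16 raster (cell size 1/16)."""
    occ = np.zeros((16, 16), dtype=bool)
    occ[8, 0:4] = True                     # stem from the bottom edge
    occ[6:11, 4] = True                    # loop bottom
    occ[6:11, 8] = True                    # loop top
    occ[6, 4:9] = True                     # loop left side
    occ[10, 4:9] = True                    # loop right side
    occ[8, 9:13] = True                    # main upper branch above the loop
    occ[6, 9:11] = True                    # small upper branch (local max)
    occ[9:12, 2] = True                    # lower side branch ...
    occ[11, 1] = True                      # ... hanging below its junction
    return OccupancyGrid(16, 1.0, occ), 1.0 / 16


@pytest.fixture(scope="session")
def desk_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def study(desk_config):
    """Shared step-1 stage (training sets + selections) for the heavy
    end-to-end checks; built once per session."""
    from angiotop.experiments import build_study

    return build_study(desk_config, seed=0)
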