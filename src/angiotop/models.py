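"""Model parameters and prior distributions.

Each of the three snail-trail models exposes four inferred parameters: two
movement parameters specific to the model, plus the two branching parameters
shared by all models —

* AC (Anderson--Chaplain, lattice): chemotaxis ``chi``, haptotaxis ``rho``;
* SL (Stokes--Lauffenburger, off-lattice velocity SDE): chemotactic
  sensitivity ``kappa``, noise magnitude ``sigma``;
* PS (Plank--Sleeman, constant-speed turning walk): chemotactic turning bias
  ``dc``, turning rate ``dr``;
* all models: minimum branching age ``abr`` (time units) and VEGF branching
  threshold ``cbr`` (nondimensional concentration).

Priors are independent uniforms per parameter.  The default ranges below are
editable placeholders spanning each model's qualitative regimes (weak to
strong chemotaxis, sparse to dense branching); they are configuration, not
fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

__all__ = ["MODEL_IDS", "PARAM_NAMES", "ModelParams", "Prior", "default_prior"]

MODEL_IDS: Tuple[str, ...] = ("ac", "sl", "ps")

#: inference-parameter names per model, in fixed order
PARAM_NAMES: Dict[str, Tuple[str, ...]] = {
    "ac": ("chi", "rho", "abr", "cbr"),
    "sl": ("kappa", "sigma", "abr", "cbr"),
    "ps": ("dc", "dr", "abr", "cbr"),
}


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector for one model.

    ``values`` holds exactly the four inferred parameters of ``model_id`` in
    the order of :data:`PARAM_NAMES`.
    """

    model_id: str
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        names = PARAM_NAMES[self.model_id]
        if len(self.values) != len(names):
            raise ValueError(
                f"{self.model_id} expects {len(names)} parameters {names}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        for name, v in zip(names, self.values):
            if name != "cbr" and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self["cbr"] <= 1.0:
            raise ValueError("cbr must lie in [0, 1]")

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[PARAM_NAMES[self.model_id].index(name)]
        except ValueError as exc:
            raise KeyError(name) from exc

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(PARAM_NAMES[self.model_id], self.values))

    @classmethod
    def from_dict(cls, model_id: str, mapping: Mapping[str, float]) -> "ModelParams":
        return cls(model_id, tuple(mapping[n] for n in PARAM_NAMES[model_id]))


class Prior:
    """Independent uniform priors over a model's parameter vector.

    Parameters
    ----------
    model_id : str
    bounds : mapping of parameter name -> (lower, upper)
        Must cover exactly the model's parameter names, with lower < upper.
    """

    def __init__(self, model_id: str, bounds: Mapping[str, Tuple[float, float]]):
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {model_id!r}")
        names = PARAM_NAMES[model_id]
        if set(bounds) != set(names):
            raise ValueError(f"bounds must name exactly {names}")
        self.model_id = model_id
        self.names = names
        self.lower = np.array([bounds[n][0] for n in names], dtype=float)
        self.upper = np.array([bounds[n][1] for n in names], dtype=float)
        if np.any(self.lower >= self.upper):
            raise ValueError("each prior bound needs lower < upper")
        self._log_vol = float(np.sum(np.log(self.upper - self.lower)))

    @property
    def dim(self) -> int:
        return len(self.names)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` parameter vectors, shape ``(n, dim)``."""
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def in_support(self, theta: Sequence[float]) -> bool:
        t = np.asarray(theta, dtype=float)
        return bool(np.all(t >= self.lower) and np.all(t <= self.upper))

    def logpdf(self, theta: Sequence[float]) -> float:
        return -self._log_vol if self.in_support(theta) else -np.inf

    def params(self, theta: Sequence[float]) -> ModelParams:
        return ModelParams(self.model_id, tuple(float(v) for v in theta))

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)


#: placeholder prior ranges spanning each model's qualitative regimes
_DEFAULT_BOUNDS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "ac": {"chi": (0.0, 1.5), "rho": (0.0, 1.0),
           "abr": (5.0, 80.0), "cbr": (0.1, 0.9)},
    "sl": {"kappa": (0.0, 0.3), "sigma": (0.02, 0.5),
           "abr": (0.5, 8.0), "cbr": (0.1, 0.9)},
    # dr upper bound keeps the turning probabilities valid (dr*dt*cosh(dc)<1)
    # across the whole dc range at the default dt
    "ps": {"dc": (0.0, 2.0), "dr": (0.05, 0.25),
           "abr": (5.0, 80.0), "cbr": (0.1, 0.9)},
}


def default_prior(model_id: str) -> Prior:
    """Default prior for one model (editable placeholder ranges)."""
    return Prior(model_id, _DEFAULT_BOUNDS[model_id])
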