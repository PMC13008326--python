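"""Conjugate Gaussian toy problem for validating the ABC-SMC machinery.

The "model" draws ``n_obs`` observations from ``N(theta, noise_sd^2)`` and
summarizes them by their sample mean.  Under a flat (wide uniform) prior the
exact posterior of ``theta`` given an observed sample mean ``m`` is
``N(m, noise_sd^2 / n_obs)`` (truncated to the prior support), which gives a
closed-form target the likelihood-free sampler must reproduce: as the
tolerance shrinks, the ABC posterior mean and variance converge to the
analytic values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import Prior

__all__ = ["GaussianMeanToy"]


@dataclass(frozen=True)
class GaussianMeanToy:
    """One-parameter location model with known Gaussian noise."""

    noise_sd: float = 1.0
    n_obs: int = 10
    lower: float = -10.0
    upper: float = 10.0

    def prior(self) -> Prior:
        # reuse the uniform-prior container on a 1-parameter "model"
        prior = Prior.__new__(Prior)
        prior.model_id = "ac"  # container only; the toy is model-agnostic
        prior.names = ("theta",)
        prior.lower = np.array([self.lower])
        prior.upper = np.array([self.upper])
        prior._log_vol = float(np.log(self.upper - self.lower))
        return prior

    def simulate_mean(self, theta: np.ndarray, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        x = rng.normal(float(np.atleast_1d(theta)[0]), self.noise_sd,
                       size=self.n_obs)
        return np.array([x.mean()])

    def analytic_posterior(self, observed_mean: float) -> tuple[float, float]:
        """(mean, sd) of the flat-prior posterior given the observed mean."""
        return observed_mean, self.noise_sd / np.sqrt(self.n_obs)
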