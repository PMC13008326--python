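"""Likelihood-free parameter inference by ABC-SMC.

Step 2 of the pipeline.  Given observed data ``D*`` (here: r replicate
simulations at unknown parameters), the posterior ``p(theta | D*)`` of one
model is approximated by sequential Monte Carlo over a decreasing tolerance
schedule: candidate parameters are accepted when the distance

    nu(D*, D_i) = mean over replicates j of || (x*_j - x_i) / s ||_2

falls below the current tolerance, where ``x_i`` is the simulation's feature
vector restricted to the ``ns`` selected summary statistics and ``s`` is the
per-statistic scale — the largest absolute value of that statistic in the
training data — so every statistic contributes comparably.

The SMC sampler follows the standard population scheme: generation 1 samples
the prior (tolerance infinity by default); each later generation resamples
the previous particles by weight, perturbs them with a component-wise
Gaussian kernel whose variance is twice the weighted empirical variance of
the previous generation, rejects proposals outside the prior support, and
accepts particles below the generation tolerance — the quantile of the
previous generation's accepted distances, so tolerances decrease
automatically.  Importance weights follow the usual prior-over-mixture form.

The module is organized like a statsmodels estimator: :class:`ABCSMC` is the
model object, ``fit`` returns :class:`SMCResults` carrying the particle
populations, a weighted-KDE posterior, highest-posterior-density queries and
a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .models import Prior

__all__ = [
    "DistanceSpec",
    "make_distance",
    "abc_rejection",
    "ABCSMC",
    "SMCResults",
    "ParticlePopulation",
    "posterior_density",
    "WeightedKDE",
]

logger = logging.getLogger(__name__)

#: simulator signature: (theta, seed) -> feature vector aligned to the distance
Simulator = Callable[[np.ndarray, int], np.ndarray]


@dataclass
class DistanceSpec:
    """Scaled Euclidean distance to observed replicates over selected features."""

    feature_names: List[str]
    scales: np.ndarray
    observed: np.ndarray  # (r, ns) scaled replicate feature vectors

    @property
    def n_replicates(self) -> int:
        return len(self.observed)

    def __call__(self, x: np.ndarray) -> float:
        """Distance of one feature vector (selected columns, raw scale)."""
        xs = np.asarray(x, dtype=float) / self.scales
        return float(np.mean(np.linalg.norm(self.observed - xs[None, :], axis=1)))

    def restrict(self, features: pd.Series | pd.DataFrame) -> np.ndarray:
        """Extract the selected columns, in distance order."""
        if isinstance(features, pd.Series):
            return features[self.feature_names].to_numpy(dtype=float)
        return features[self.feature_names].to_numpy(dtype=float)


def make_distance(
    training_features: pd.DataFrame,
    selected: Sequence[str],
    observed: pd.DataFrame,
) -> DistanceSpec:
    """Build the ABC distance from training scales and observed replicates.

    Scales are max-abs over the training table, so scaled training features
    lie in ``[-1, 1]``; statistics whose training maximum is zero carry no
    information at this scale and are dropped with a warning.
    """
    selected = list(selected)
    missing = [c for c in selected if c not in training_features.columns]
    if missing:
        raise KeyError(f"selected features missing from training table: {missing[:5]}")
    if len(observed) < 1:
        raise ValueError("need at least one observed replicate")
    scales = training_features[selected].abs().max(axis=0).to_numpy(dtype=float)
    keep = scales > 0
    if not keep.all():
        dropped = [s for s, k in zip(selected, keep) if not k]
        logger.warning("dropping %d zero-scale features: %s",
                       len(dropped), dropped[:5])
        selected = [s for s, k in zip(selected, keep) if k]
        scales = scales[keep]
    obs = observed[selected].to_numpy(dtype=float) / scales[None, :]
    return DistanceSpec(feature_names=selected, scales=scales, observed=obs)


@dataclass
class ParticlePopulation:
    """One ABC-SMC generation."""

    t: int
    thetas: np.ndarray           # (N, dim)
    weights: np.ndarray          # normalized, sum 1
    distances: np.ndarray
    epsilon: float
    acceptance_rate: float
    n_sims: int

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("negative particle weight")
        total = self.weights.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            self.weights = self.weights / total

    @property
    def ess(self) -> float:
        """Effective sample size of the importance weights."""
        return float(1.0 / np.sum(self.weights ** 2))


def abc_rejection(
    prior: Prior,
    simulator: Simulator,
    distance: Callable[[np.ndarray], float],
    epsilon: float,
    n_draws: int,
    seed: int,
) -> pd.DataFrame:
    """Plain ABC rejection: draw from the prior, keep distances below epsilon.

    Returns a table of accepted parameters with their distances; the
    acceptance rate is stored in ``frame.attrs['acceptance_rate']``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 2]))
    thetas = prior.rvs(n_draws, rng)
    seeds = rng.integers(0, 2 ** 31, size=n_draws)
    rows = []
    for theta, s in zip(thetas, seeds):
        d = distance(simulator(theta, int(s)))
        if d < epsilon:
            rows.append(np.append(theta, d))
    if not rows:
        raise RuntimeError(
            f"no acceptances in {n_draws} draws at epsilon={epsilon}; "
            "increase epsilon")
    out = pd.DataFrame(rows, columns=list(prior.names) + ["distance"])
    out.attrs["acceptance_rate"] = len(rows) / n_draws
    return out


class ABCSMC:
    """ABC sequential Monte Carlo sampler for one model.

    Parameters
    ----------
    prior : Prior
        Independent uniform prior over the model's parameters.
    simulator : callable ``(theta, seed) -> feature vector``
        Simulates the model and returns the summary-statistic vector the
        distance expects.
    distance : callable ``(features) -> float``
        Typically a :class:`DistanceSpec`.
    n_particles : int
        Particles per generation (N >= 50).
    n_generations : int
        Maximum number of generations.
    epsilon0 : float
        Tolerance of generation 1 (default infinity: plain prior sample).
    quantile : float
        Adaptive schedule: the next tolerance is this quantile of the
        current generation's accepted distances.
    min_acceptance : float
        Stop early when a generation's acceptance rate falls below this.
    """

    def __init__(
        self,
        prior: Prior,
        simulator: Simulator,
        distance: Callable[[np.ndarray], float],
        *,
        n_particles: int = 200,
        n_generations: int = 5,
        epsilon0: float = np.inf,
        quantile: float = 0.5,
        min_acceptance: float = 0.015,
        kernel_inflation: float = 2.0,
    ):
        if n_particles < 50:
            raise ValueError("need at least 50 particles")
        if not 0 < quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        self.prior = prior
        self.simulator = simulator
        self.distance = distance
        self.n_particles = n_particles
        self.n_generations = n_generations
        self.epsilon0 = epsilon0
        self.quantile = quantile
        self.min_acceptance = min_acceptance
        self.kernel_inflation = kernel_inflation

    def fit(self, seed: int = 0) -> "SMCResults":
        """Run the SMC schedule; returns the results object."""
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 3]))
        N = self.n_particles
        dim = self.prior.dim
        populations: List[ParticlePopulation] = []
        status = "completed"

        # generation 1: prior sample at epsilon0
        thetas = np.empty((N, dim))
        dists = np.empty(N)
        n_sims = 0
        i = 0
        max_draws = int(N / max(self.min_acceptance, 1e-6))
        while i < N and n_sims < max_draws:
            theta = self.prior.rvs(1, rng)[0]
            d = self.distance(self.simulator(theta, int(rng.integers(2 ** 31))))
            n_sims += 1
            if d < self.epsilon0:
                thetas[i] = theta
                dists[i] = d
                i += 1
        if i < N:
            raise RuntimeError("generation 1 failed to accept enough particles; "
                               "increase epsilon0")
        weights = np.full(N, 1.0 / N)
        populations.append(ParticlePopulation(
            t=1, thetas=thetas.copy(), weights=weights.copy(),
            distances=dists.copy(), epsilon=float(self.epsilon0),
            acceptance_rate=N / n_sims, n_sims=n_sims))

        eps = float(np.quantile(dists, self.quantile))
        for t in range(2, self.n_generations + 1):
            prev = populations[-1]
            if np.isfinite(prev.epsilon):
                eps = min(eps, 0.95 * prev.epsilon)
            var = self.kernel_inflation * _weighted_var(prev.thetas, prev.weights)
            var = np.maximum(var, 1e-12)
            std = np.sqrt(var)
            new_thetas = np.empty((N, dim))
            new_dists = np.empty(N)
            accepted = 0
            n_sims = 0
            max_draws = int(N / max(self.min_acceptance, 1e-6))
            while accepted < N and n_sims < max_draws:
                j = rng.choice(len(prev.thetas), p=prev.weights)
                theta = prev.thetas[j] + rng.standard_normal(dim) * std
                if not self.prior.in_support(theta):
                    continue
                d = self.distance(
                    self.simulator(theta, int(rng.integers(2 ** 31))))
                n_sims += 1
                if d < eps:
                    new_thetas[accepted] = theta
                    new_dists[accepted] = d
                    accepted += 1
            if accepted < N:
                status = (f"stopped at generation {t - 1}: acceptance rate "
                          f"fell below {self.min_acceptance}")
                logger.warning(status)
                break
            w = np.empty(N)
            for k in range(N):
                kern = np.exp(-0.5 * np.sum(
                    (new_thetas[k] - prev.thetas) ** 2 / var, axis=1))
                kern /= np.prod(np.sqrt(2 * np.pi * var))
                denom = float(np.dot(prev.weights, kern))
                w[k] = math.exp(self.prior.logpdf(new_thetas[k])) / max(denom, 1e-300)
            w /= w.sum()
            populations.append(ParticlePopulation(
                t=t, thetas=new_thetas, weights=w, distances=new_dists,
                epsilon=eps, acceptance_rate=N / n_sims, n_sims=n_sims))
            eps = float(np.quantile(new_dists, self.quantile))

        return SMCResults(prior=self.prior, populations=populations,
                          status=status)


def _weighted_var(thetas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mean = weights @ thetas
    return weights @ (thetas - mean) ** 2


def _weighted_quantile(values: np.ndarray, weights: np.ndarray,
                       q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, v))


class WeightedKDE:
    """Weighted Gaussian kernel density over the final particle population."""

    def __init__(self, thetas: np.ndarray, weights: np.ndarray):
        thetas = np.asarray(thetas, dtype=float)
        if len(np.unique(thetas, axis=0)) < 2:
            raise ValueError("cannot fit a KDE to identical particles")
        self.thetas = thetas
        self.weights = np.asarray(weights, dtype=float)
        self._kde = gaussian_kde(thetas.T, weights=self.weights)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self._kde(pts.T)

    def pair_marginal(self, i: int, j: int, grid_i: np.ndarray,
                      grid_j: np.ndarray) -> np.ndarray:
        """Evaluate the 2-D marginal KDE of components (i, j) on a mesh."""
        kde2 = gaussian_kde(self.thetas[:, [i, j]].T, weights=self.weights)
        gi, gj = np.meshgrid(grid_i, grid_j, indexing="ij")
        return kde2(np.vstack([gi.ravel(), gj.ravel()])).reshape(gi.shape)

    def hpd_level(self, level: float = 0.95) -> float:
        """Density threshold of the ``level`` highest-density region.

        The region is estimated from the particles: a point belongs to the
        95% HPD region when its density is at least the weighted 5th
        percentile of the density evaluated at the particles themselves.
        Particle densities are corrected leave-one-out — each particle's own
        kernel bump is removed before taking the quantile — since with a few
        hundred particles in several dimensions the self-contribution
        dominates the density at a particle and the naive threshold excludes
        genuinely supported points.
        """
        dens = self.evaluate(self.thetas)
        d = self.thetas.shape[1]
        k0 = 1.0 / np.sqrt((2 * np.pi) ** d
                           * np.linalg.det(self._kde.covariance))
        loo = np.maximum((dens - self.weights * k0)
                         / np.maximum(1.0 - self.weights, 1e-12), 0.0)
        return _weighted_quantile(loo, self.weights, 1.0 - level)

    def hpd_contains(self, theta: np.ndarray, level: float = 0.95) -> bool:
        return bool(self.evaluate(np.asarray(theta))[0] >= self.hpd_level(level))


def posterior_density(population: ParticlePopulation) -> WeightedKDE:
    """Weighted Gaussian KDE over one (typically final) SMC population."""
    return WeightedKDE(population.thetas, population.weights)


@dataclass
class SMCResults:
    """Results of an ABC-SMC fit.

    Carries every generation's particles, weights, distances and tolerance;
    the posterior approximation is the weighted final population.
    """

    prior: Prior
    populations: List[ParticlePopulation]
    status: str = "completed"
    _kde: Optional[WeightedKDE] = field(default=None, repr=False)

    @property
    def final(self) -> ParticlePopulation:
        return self.populations[-1]

    @property
    def param_names(self) -> List[str]:
        return list(self.prior.names)

    @property
    def epsilons(self) -> List[float]:
        return [p.epsilon for p in self.populations]

    def posterior_density(self) -> WeightedKDE:
        if self._kde is None:
            self._kde = posterior_density(self.final)
        return self._kde

    def posterior_mean(self) -> np.ndarray:
        return self.final.weights @ self.final.thetas

    def posterior_var(self) -> np.ndarray:
        return _weighted_var(self.final.thetas, self.final.weights)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        lo = (1 - level) / 2
        out = np.empty((self.prior.dim, 2))
        for k in range(self.prior.dim):
            out[k, 0] = _weighted_quantile(self.final.thetas[:, k],
                                           self.final.weights, lo)
            out[k, 1] = _weighted_quantile(self.final.thetas[:, k],
                                           self.final.weights, 1 - lo)
        return out

    def hpd_contains(self, theta: np.ndarray, level: float = 0.95) -> bool:
        """Is a parameter vector inside the joint HPD region?"""
        return self.posterior_density().hpd_contains(theta, level)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw parameter vectors from the weighted final population."""
        idx = rng.choice(len(self.final.thetas), size=n, p=self.final.weights)
        return self.final.thetas[idx]

    def to_frame(self) -> pd.DataFrame:
        """All generations as one tidy table."""
        frames = []
        for pop in self.populations:
            df = pd.DataFrame(pop.thetas, columns=self.param_names)
            df["weight"] = pop.weights
            df["distance"] = pop.distances
            df["generation"] = pop.t
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd and central 95% interval."""
        ci = self.credible_interval(0.95)
        return pd.DataFrame({
            "mean": self.posterior_mean(),
            "sd": np.sqrt(self.posterior_var()),
            "ci2.5": ci[:, 0],
            "ci97.5": ci[:, 1],
        }, index=self.param_names)

    def __str__(self) -> str:
        lines = [
            "ABC-SMC results",
            f"  model: {self.prior.model_id}   status: {self.status}",
            f"  generations: {len(self.populations)}   "
            f"particles: {len(self.final.thetas)}",
            f"  tolerances: {np.round(self.epsilons, 4).tolist()}",
            "",
            self.summary().round(4).to_string(),
        ]
        return "\n".join(lines)
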