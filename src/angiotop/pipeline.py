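"""End-to-end orchestration of the three-step inference pipeline.

Step 1 trains per-parameter regression forests on prior-predictive
simulations and selects the ``ns`` most informative summary statistics per
model; step 2 fits each model to the observed replicates by ABC-SMC over the
scaled selected statistics; step 3 estimates the model posterior with the
classification + regression forest pair on the cross-model common
statistics.

Synthetic test-cases play the role of observed data: ``r`` replicate
simulations (default 10) at known parameters, so both parameter recovery
(is the truth inside the posterior?) and model recovery (is the generating
model identified?) can be scored.

Every stage derives its randomness from one master seed through named
streams, so a full pipeline run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .abcsmc import ABCSMC, DistanceSpec, SMCResults, make_distance
from .domain import DomainConfig
from .model_choice import ModelChoice, common_features
from .models import MODEL_IDS, ModelParams, Prior, default_prior
from .selection import (Selection, TrainingSet, build_training_set,
                        derive_seeds, rank_all, select_top_features)
from .simulators import SimulationResult, SimulatorSettings, simulate
from .summaries import FeatureConfig, featurize_many

__all__ = [
    "PipelineConfig",
    "TestCase",
    "make_testcase",
    "run_pipeline",
    "PipelineResult",
    "RunManifest",
]

logger = logging.getLogger(__name__)

_DESK_DOMAIN = {
    "ac": DomainConfig(lattice_resolution=33, n_initial_tips=5,
                       n_timesteps=200, dt=1.0),
    "sl": DomainConfig(lattice_resolution=33, n_initial_tips=5,
                       n_timesteps=300, dt=0.05),
    "ps": DomainConfig(lattice_resolution=33, n_initial_tips=5,
                       n_timesteps=300, dt=1.0),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Scales and settings of a full pipeline run.

    The defaults are desk scale — small enough to iterate on a laptop while
    preserving the method's behaviour; ``full_scale()`` restores the
    full-study training-set size (n = 10,000 prior draws per model).
    """

    n_train: int = 300
    ns: int = 100
    rf_trees: int = 200
    n_particles: int = 200
    n_generations: int = 5
    smc_quantile: float = 0.5
    min_acceptance: float = 0.02
    n_replicates: int = 10
    domains: Dict[str, DomainConfig] = field(
        default_factory=lambda: dict(_DESK_DOMAIN))
    settings: SimulatorSettings = SimulatorSettings(max_tips=128)
    feature_config: FeatureConfig = FeatureConfig()

    @classmethod
    def full_scale(cls) -> "PipelineConfig":
        domains = {m: replace(d, lattice_resolution=51)
                   for m, d in _DESK_DOMAIN.items()}
        return cls(n_train=10_000, rf_trees=500, n_particles=200,
                   n_generations=6, domains=domains,
                   settings=SimulatorSettings())

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["domains"] = {m: asdict(c) for m, c in self.domains.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        domains = {m: DomainConfig(**c) for m, c in raw.pop("domains", {}).items()}
        settings = SimulatorSettings(**raw.pop("settings", {}))
        feature_config = FeatureConfig(**raw.pop("feature_config", {}))
        base = cls(settings=settings, feature_config=feature_config, **raw)
        if domains:
            merged = dict(base.domains)
            merged.update(domains)
            base = replace(base, domains=merged)
        return base


@dataclass
class TestCase:
    """Synthetic observed data: r replicates at known parameters."""

    model_id: str
    true_params: ModelParams
    replicates: List[SimulationResult] = field(repr=False)
    features: pd.DataFrame = field(repr=False)
    label: str = ""
    seed: int = 0

    @property
    def r(self) -> int:
        return len(self.replicates)


def make_testcase(
    model_id: str,
    true_params: ModelParams,
    r: int,
    config: PipelineConfig,
    seed: int,
    label: str = "",
) -> TestCase:
    """Simulate ``r`` replicates at known parameters and featurize them."""
    if r < 1:
        raise ValueError("need at least one replicate")
    seeds = derive_seeds(seed, r, stream=11)
    sims = [simulate(model_id, true_params, config.domains[model_id], int(s),
                     config.settings) for s in seeds]
    feats = featurize_many(sims, config.feature_config)
    return TestCase(model_id=model_id, true_params=true_params,
                    replicates=sims, features=feats,
                    label=label or f"{model_id}-testcase", seed=seed)


def _model_simulator(model_id: str, prior: Prior, config: PipelineConfig,
                     feature_names: List[str]):
    """Closure mapping (theta, seed) to the selected feature vector."""
    from .summaries import featurize

    domain = config.domains[model_id]

    def sim(theta: np.ndarray, seed: int) -> np.ndarray:
        result = simulate(model_id, prior.params(theta), domain, int(seed),
                          config.settings)
        feats = featurize(result, config.feature_config)
        return feats[feature_names].to_numpy(dtype=float)

    return sim


@dataclass
class PipelineResult:
    """Everything the three steps produce for one test-case."""

    testcase: TestCase
    selections: Dict[str, Selection]
    common: List[str]
    smc: Dict[str, SMCResults]
    model_posterior: Dict
    predictions: Dict[str, SimulationResult] = field(default_factory=dict)
    manifest: Optional["RunManifest"] = None


def run_pipeline(
    testcase: TestCase,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    priors: Optional[Dict[str, Prior]] = None,
    training: Optional[Dict[str, TrainingSet]] = None,
    selections: Optional[Dict[str, Selection]] = None,
    fit_models: Optional[List[str]] = None,
) -> PipelineResult:
    """Run steps 1-3 against one test-case.

    Training sets and selections may be passed in (they are shared between
    test-cases); anything missing is built on demand from ``seed``.
    ``fit_models`` restricts the ABC-SMC stage to a subset of models (the
    model-choice stage always uses all three).
    """
    priors = priors or {m: default_prior(m) for m in MODEL_IDS}
    if training is None:
        training = {}
    for m in MODEL_IDS:
        if m not in training:
            logger.info("building training set for %s (n=%d)", m, config.n_train)
            training[m] = build_training_set(
                m, priors[m], config.n_train, config.domains[m],
                int(derive_seeds(seed, 3, stream=21)[MODEL_IDS.index(m)]),
                config.settings, config.feature_config)

    if selections is None:
        selections = {}
    for m in MODEL_IDS:
        if m not in selections:
            rankings = rank_all(training[m], n_trees=config.rf_trees, seed=seed)
            selections[m] = select_top_features(rankings, ns=config.ns)

    common = common_features({m: s.selected for m, s in selections.items()})

    smc: Dict[str, SMCResults] = {}
    for m in (fit_models or MODEL_IDS):
        dist = make_distance(training[m].features, selections[m].selected,
                             testcase.features)
        simfn = _model_simulator(m, priors[m], config, dist.feature_names)
        sampler = ABCSMC(priors[m], simfn, dist,
                         n_particles=config.n_particles,
                         n_generations=config.n_generations,
                         quantile=config.smc_quantile,
                         min_acceptance=config.min_acceptance)
        smc[m] = sampler.fit(seed=int(derive_seeds(seed, 3, stream=31)
                                      [MODEL_IDS.index(m)]))

    pooled = pd.concat([training[m].features[common] for m in MODEL_IDS],
                       ignore_index=True)
    labels = np.concatenate([[m] * training[m].n for m in MODEL_IDS])
    choice = ModelChoice(pooled, labels, n_trees=config.rf_trees,
                         seed=seed).fit()
    posterior = choice.predict_replicates(testcase.features[common])

    # posterior-predictive illustration: one simulation at a posterior draw
    predictions: Dict[str, SimulationResult] = {}
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 41]))
    for m, res in smc.items():
        theta = res.sample(1, rng)[0]
        predictions[m] = simulate(m, priors[m].params(theta),
                                  config.domains[m],
                                  int(rng.integers(2 ** 31)), config.settings)

    manifest = RunManifest.collect(config, seed, testcase, smc)
    return PipelineResult(testcase=testcase, selections=selections,
                          common=common, smc=smc, model_posterior=posterior,
                          predictions=predictions, manifest=manifest)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    master_seed: int
    testcase_label: str
    testcase_seed: int
    epsilon_schedules: Dict[str, List[float]]
    acceptance_rates: Dict[str, List[float]]

    @classmethod
    def collect(cls, config: PipelineConfig, seed: int, testcase: TestCase,
                smc: Dict[str, SMCResults]) -> "RunManifest":
        return cls(
            config_hash=config.config_hash(),
            master_seed=seed,
            testcase_label=testcase.label,
            testcase_seed=testcase.seed,
            epsilon_schedules={m: [float(e) for e in r.epsilons]
                               for m, r in smc.items()},
            acceptance_rates={m: [float(p.acceptance_rate)
                                  for p in r.populations]
                              for m, r in smc.items()},
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))
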