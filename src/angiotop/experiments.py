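"""Desk-scale validation experiments.

Bundles the study design used to validate the pipeline end to end: a shared
training stage (prior draws, simulations, feature selection per model), two
synthetic test-cases per model spanning low- and high-branching regimes, a
parameter-recovery experiment (is the true parameter vector inside the
posterior's 95% highest-density region?) and a model-recovery experiment
(does the forest pair identify the generating model?).

The built-in test-case parameters are package choices spanning each model's
qualitative regimes — one strongly chemotactic, densely branching case and
one weakly guided, sparse case per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .abcsmc import ABCSMC, SMCResults, make_distance
from .model_choice import ModelChoice, ModelChoiceResults, common_features
from .models import MODEL_IDS, ModelParams, Prior, default_prior
from .pipeline import PipelineConfig, TestCase, _model_simulator, make_testcase
from .selection import Selection, TrainingSet, build_training_set, \
    derive_seeds, rank_all, select_top_features

__all__ = ["TESTCASE_PARAMS", "Study", "build_study", "fit_testcase",
           "recovery_experiment", "model_recovery_experiment"]

#: two test-cases per model: (dense/chemotactic, sparse/weakly guided)
TESTCASE_PARAMS: Dict[str, List[tuple]] = {
    "ac": [(0.9, 0.3, 15.0, 0.25), (0.4, 0.6, 50.0, 0.6)],
    "sl": [(0.15, 0.1, 1.0, 0.25), (0.05, 0.35, 5.0, 0.6)],
    "ps": [(1.2, 0.08, 15.0, 0.25), (0.4, 0.2, 50.0, 0.6)],
}


@dataclass
class Study:
    """Shared training stage of the validation experiments."""

    config: PipelineConfig
    seed: int
    priors: Dict[str, Prior]
    training: Dict[str, TrainingSet] = field(repr=False)
    selections: Dict[str, Selection]
    common: List[str]
    _choice: Optional[ModelChoiceResults] = field(default=None, repr=False)

    def model_choice(self) -> ModelChoiceResults:
        """Classifier + error regressor on the pooled common features."""
        if self._choice is None:
            pooled = pd.concat(
                [self.training[m].features[self.common] for m in MODEL_IDS],
                ignore_index=True)
            labels = np.concatenate(
                [[m] * self.training[m].n for m in MODEL_IDS])
            self._choice = ModelChoice(pooled, labels,
                                       n_trees=self.config.rf_trees,
                                       seed=self.seed).fit()
        return self._choice


def build_study(config: PipelineConfig = PipelineConfig(),
                seed: int = 0) -> Study:
    """Run step 1 for all three models: training sets and selections."""
    priors = {m: default_prior(m) for m in MODEL_IDS}
    training = {}
    selections = {}
    for k, m in enumerate(MODEL_IDS):
        training[m] = build_training_set(
            m, priors[m], config.n_train, config.domains[m],
            int(derive_seeds(seed, 3, stream=21)[k]),
            config.settings, config.feature_config)
        rankings = rank_all(training[m], n_trees=config.rf_trees, seed=seed)
        selections[m] = select_top_features(rankings, ns=config.ns)
    common = common_features({m: s.selected for m, s in selections.items()})
    return Study(config=config, seed=seed, priors=priors, training=training,
                 selections=selections, common=common)


def fit_testcase(study: Study, testcase: TestCase, model_id: str,
                 seed: int = 0) -> SMCResults:
    """Step 2: ABC-SMC fit of one model to one test-case's replicates."""
    cfg = study.config
    dist = make_distance(study.training[model_id].features,
                         study.selections[model_id].selected,
                         testcase.features)
    simfn = _model_simulator(model_id, study.priors[model_id], cfg,
                             dist.feature_names)
    sampler = ABCSMC(study.priors[model_id], simfn, dist,
                     n_particles=cfg.n_particles,
                     n_generations=cfg.n_generations,
                     quantile=cfg.smc_quantile,
                     min_acceptance=cfg.min_acceptance)
    return sampler.fit(seed=seed)


def recovery_experiment(study: Study, model_id: str, case: int = 0,
                        seed: int = 0, level: float = 0.95) -> Dict:
    """Fit a model to its own synthetic test-case; score HPD coverage."""
    theta = TESTCASE_PARAMS[model_id][case]
    tc = make_testcase(model_id, ModelParams(model_id, theta),
                       study.config.n_replicates, study.config,
                       seed=int(derive_seeds(seed, 2, stream=51)[case]))
    res = fit_testcase(study, tc, model_id, seed=seed)
    covered = res.hpd_contains(np.asarray(theta), level=level)
    return {"model": model_id, "true_theta": theta, "results": res,
            "covered": bool(covered), "testcase": tc}


def model_recovery_experiment(study: Study, seed: int = 0) -> Dict:
    """Step 3 on all six test-cases; score model identification."""
    choice = study.model_choice()
    records = []
    for m in MODEL_IDS:
        for case, theta in enumerate(TESTCASE_PARAMS[m]):
            tc = make_testcase(m, ModelParams(m, theta),
                               study.config.n_replicates, study.config,
                               seed=int(derive_seeds(seed, 10, stream=61)
                                        [2 * MODEL_IDS.index(m) + case]))
            post = choice.predict_replicates(tc.features[study.common])
            records.append({
                "true_model": m, "case": case,
                "predicted_model": post["predicted_model"],
                "posterior_probability": post["posterior_probability"],
                "correct": post["predicted_model"] == m,
                "true_model_mean_probability": float(np.mean(
                    [p["votes"].get(m, 0.0) for p in post["per_replicate"]])),
            })
    n_correct = sum(r["correct"] for r in records)
    mean_p_true = float(np.mean(
        [r["posterior_probability"] for r in records if r["correct"]]
    )) if n_correct else 0.0
    return {"cases": records, "n_correct": n_correct,
            "n_cases": len(records), "mean_true_model_posterior": mean_p_true,
            "oob_error": choice.oob_error}
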