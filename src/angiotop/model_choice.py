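"""Model selection with a pair of random forests.

Step 3 of the pipeline.  Pooling the training simulations of all candidate
models, a classification random forest learns the map from (unscaled) summary
statistics to model labels; for every training record the out-of-bag (OOB)
prediction — made only by trees that did not see the record — yields a 0/1
misclassification indicator.  A regression random forest then learns the map
from summary statistics to that indicator, i.e. the local probability that
the classifier's prediction is wrong.  For observed data ``X*`` the model
posterior is estimated as

    p(m = m_hat | D*) = 1 - predicted OOB error at X*,

with ``m_hat`` the classifier's prediction.  Only statistics that rank among
the ``ns`` most informative for *every* model enter, so the comparison is not
biased toward any one model's preferred summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "common_features",
    "train_classifier",
    "train_error_regressor",
    "model_posterior",
    "ModelPosterior",
    "ModelChoice",
    "ModelChoiceResults",
]


def common_features(selected: Mapping[str, Sequence[str]]) -> List[str]:
    """Statistics selected for every model, in the first model's order.

    Raises if the intersection is empty — then ``ns`` was too small to give
    all models shared informative statistics and should be enlarged.
    """
    ids = list(selected)
    if not ids:
        raise ValueError("no selections given")
    common = set(selected[ids[0]])
    for m in ids[1:]:
        common &= set(selected[m])
    if not common:
        raise ValueError(
            "no summary statistic is informative for all models; "
            "enlarge ns so the selections overlap")
    return [f for f in selected[ids[0]] if f in common]


def train_classifier(
    X: pd.DataFrame,
    labels: Sequence[str],
    *,
    n_trees: int = 500,
    seed: int = 0,
) -> Tuple[RandomForestClassifier, np.ndarray]:
    """Fit the model-label classifier; return it with per-record OOB predictions.

    Features enter unscaled.  Requires >= 50 records per class.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two model classes")
    if counts.min() < 50:
        raise ValueError("need at least 50 records per class")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 oob_score=True, n_jobs=1)
    clf.fit(X.to_numpy(), y)
    proba = np.nan_to_num(clf.oob_decision_function_, nan=0.0)
    oob_pred = clf.classes_[proba.argmax(axis=1)]
    return clf, oob_pred


def train_error_regressor(
    X: pd.DataFrame,
    misclassified: np.ndarray,
    *,
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestRegressor:
    """Fit the regression forest of the 0/1 OOB misclassification indicator."""
    reg = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                n_jobs=1)
    reg.fit(X.to_numpy(), np.asarray(misclassified, dtype=float))
    return reg


@dataclass
class ModelPosterior:
    """Estimated model posterior for one observed feature vector."""

    predicted_model: str
    posterior_probability: float  # p(m = predicted | D*), in [0, 1]
    votes: Dict[str, float]       # per-class vote fractions (diagnostic)

    def __post_init__(self) -> None:
        self.posterior_probability = float(
            np.clip(self.posterior_probability, 0.0, 1.0))


def model_posterior(
    x: pd.Series | np.ndarray,
    classifier: RandomForestClassifier,
    regressor: RandomForestRegressor,
    feature_names: Sequence[str] | None = None,
) -> ModelPosterior:
    """Classifier prediction plus 1 - predicted OOB error at ``x``."""
    if isinstance(x, pd.Series):
        if feature_names is None:
            raise ValueError("feature_names required with a Series input")
        missing = [f for f in feature_names if f not in x.index]
        if missing:
            raise KeyError(f"observed vector lacks columns {missing[:5]}")
        xv = x[list(feature_names)].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        if feature_names is not None and len(xv) != len(feature_names):
            raise ValueError("feature-vector length mismatch")
    xv = xv.reshape(1, -1)
    pred = str(classifier.predict(xv)[0])
    err = float(np.clip(regressor.predict(xv)[0], 0.0, 1.0))
    votes = dict(zip(map(str, classifier.classes_),
                     classifier.predict_proba(xv)[0]))
    return ModelPosterior(predicted_model=pred,
                          posterior_probability=1.0 - err, votes=votes)


class ModelChoice:
    """Random-forest model-choice estimator over pooled training features.

    Parameters
    ----------
    features : DataFrame
        Pooled (unscaled) training features of all models, restricted to the
        cross-model common feature set.
    labels : sequence of str
        Generating model of each record.
    """

    def __init__(self, features: pd.DataFrame, labels: Sequence[str],
                 *, n_trees: int = 500, seed: int = 0):
        self.features = features
        self.labels = np.asarray(labels)
        self.n_trees = n_trees
        self.seed = seed

    def fit(self) -> "ModelChoiceResults":
        clf, oob_pred = train_classifier(self.features, self.labels,
                                         n_trees=self.n_trees, seed=self.seed)
        misclassified = (oob_pred != self.labels).astype(float)
        reg = train_error_regressor(self.features, misclassified,
                                    n_trees=self.n_trees, seed=self.seed + 1)
        return ModelChoiceResults(
            classifier=clf, regressor=reg,
            feature_names=list(self.features.columns),
            oob_predictions=oob_pred,
            oob_error=float(misclassified.mean()))


@dataclass
class ModelChoiceResults:
    """Fitted classifier + error regressor and their diagnostics."""

    classifier: RandomForestClassifier
    regressor: RandomForestRegressor
    feature_names: List[str]
    oob_predictions: np.ndarray = field(repr=False)
    oob_error: float = np.nan

    def predict(self, x: pd.Series | np.ndarray) -> ModelPosterior:
        return model_posterior(x, self.classifier, self.regressor,
                               self.feature_names)

    def predict_replicates(self, X: pd.DataFrame) -> Dict:
        """Classify each observed replicate; report the majority model.

        Returns the majority-vote model, the mean posterior probability over
        replicates predicting it, and the per-replicate detail.
        """
        per_rep = [self.predict(row) for _, row in X.iterrows()]
        preds = pd.Series([p.predicted_model for p in per_rep])
        majority = preds.value_counts().index[0]
        probs = [p.posterior_probability for p in per_rep
                 if p.predicted_model == majority]
        return {
            "predicted_model": str(majority),
            "posterior_probability": float(np.mean(probs)),
            "per_replicate": [
                {"predicted_model": p.predicted_model,
                 "posterior_probability": p.posterior_probability,
                 "votes": p.votes} for p in per_rep],
            "oob_error": self.oob_error,
        }

    def summary(self) -> pd.DataFrame:
        classes, counts = np.unique(self.oob_predictions, return_counts=True)
        return pd.DataFrame({
            "oob_predicted_count": counts,
        }, index=classes).assign(overall_oob_error=self.oob_error)
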