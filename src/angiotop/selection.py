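"""Training-set construction and random-forest feature selection.

Step 1 of the inference pipeline: draw parameters from the prior, simulate,
featurize, then train one regression random forest per (model, parameter) to
rank every summary statistic by its importance to predicting that parameter.
An equal number of statistics per parameter is collected round-robin into the
``ns`` most informative statistics of the model (``ns = 100`` by default),
which later define the ABC distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .domain import DomainConfig
from .models import PARAM_NAMES, Prior
from .simulators import SimulatorSettings, simulate
from .summaries import FeatureConfig, feature_direction, feature_type, featurize

__all__ = [
    "TrainingSet",
    "FeatureRanking",
    "Selection",
    "build_training_set",
    "derive_seeds",
    "rank_features",
    "rank_all",
    "select_top_features",
    "summarize_selection",
]

logger = logging.getLogger(__name__)


def derive_seeds(master_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Per-simulation seeds from a master seed (documented counter scheme).

    Seed ``i`` of stream ``k`` is ``SeedSequence([master, k]).generate_state``
    entry ``i``, folded below ``2**31``.
    """
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, int(stream)])
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2 ** 31)


@dataclass
class TrainingSet:
    """Prior draws, simulations and features for one model."""

    model_id: str
    thetas: pd.DataFrame          # n x 4, columns = parameter names
    features: pd.DataFrame        # n x n_features
    seeds: np.ndarray
    n_failed: int = 0

    def __post_init__(self) -> None:
        if len(self.thetas) != len(self.features):
            raise ValueError("thetas and features must align row by row")

    @property
    def n(self) -> int:
        return len(self.thetas)


def build_training_set(
    model_id: str,
    prior: Prior,
    n: int,
    config: DomainConfig,
    seed: int,
    settings: SimulatorSettings = SimulatorSettings(),
    feature_config: FeatureConfig = FeatureConfig(),
) -> TrainingSet:
    """Draw ``n`` parameters from the prior, simulate and featurize each.

    Fully reproducible from ``seed``; simulations that fail are skipped with
    a logged seed and reported in ``n_failed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 1]))
    thetas = prior.rvs(n, rng)
    seeds = derive_seeds(seed, n)
    rows: List[pd.Series] = []
    kept_thetas: List[np.ndarray] = []
    kept_seeds: List[int] = []
    n_failed = 0
    for theta, s in zip(thetas, seeds):
        try:
            result = simulate(model_id, prior.params(theta), config, int(s),
                              settings)
            rows.append(featurize(result, feature_config))
        except Exception:
            logger.warning("simulation failed for %s seed %d; skipped",
                           model_id, s)
            n_failed += 1
            continue
        kept_thetas.append(theta)
        kept_seeds.append(int(s))
    if not rows:
        raise RuntimeError(f"all {n} simulations failed for model {model_id}")
    return TrainingSet(
        model_id=model_id,
        thetas=pd.DataFrame(kept_thetas, columns=list(prior.names)),
        features=pd.DataFrame(rows).reset_index(drop=True),
        seeds=np.asarray(kept_seeds),
        n_failed=n_failed,
    )


@dataclass
class FeatureRanking:
    """Importance ranking of every feature for one (model, parameter)."""

    model_id: str
    parameter: str
    table: pd.DataFrame = field(repr=False)  # columns: feature, importance
    oob_r2: float = np.nan

    @property
    def ordered_features(self) -> List[str]:
        return list(self.table["feature"])


def rank_features(
    train: TrainingSet | pd.DataFrame,
    parameter: str | np.ndarray,
    *,
    n_trees: int = 500,
    seed: int = 0,
    model_id: str = "",
) -> FeatureRanking:
    """Train a regression forest of a parameter on the features; rank by
    mean-impurity-decrease importance.

    Importances are non-negative and sum to one; ties are broken by feature
    name (lexicographic) so the ranking is deterministic.  The out-of-bag R^2
    is reported for diagnostics.  Requires >= 50 records and a non-constant
    response.
    """
    if isinstance(train, TrainingSet):
        X = train.features
        y = train.thetas[parameter].to_numpy()
        model_id = model_id or train.model_id
        pname = str(parameter)
    else:
        X = train
        y = np.asarray(parameter, dtype=float)
        pname = "response"
    if len(X) < 50:
        raise ValueError("need at least 50 training records")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to rank")
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                   oob_score=True, n_jobs=1)
    forest.fit(X.to_numpy(), y)
    table = pd.DataFrame({
        "feature": X.columns,
        "importance": forest.feature_importances_,
    }).sort_values(["importance", "feature"], ascending=[False, True],
                   kind="mergesort").reset_index(drop=True)
    return FeatureRanking(model_id=model_id, parameter=pname, table=table,
                          oob_r2=float(forest.oob_score_))


@dataclass
class Selection:
    """The ``ns`` selected statistics of a model, with per-parameter credit."""

    model_id: str
    selected: List[str]
    per_parameter: Dict[str, List[str]]


def select_top_features(
    rankings: Mapping[str, FeatureRanking] | Sequence[FeatureRanking],
    ns: int = 100,
    model_id: Optional[str] = None,
) -> Selection:
    """Round-robin selection of ``ns`` distinct features across parameters.

    Walks the per-parameter rankings in parameter order, taking from each the
    highest-ranked feature not yet selected, until ``ns`` distinct names are
    collected — an equal number per parameter up to duplicates.  ``ns`` must
    be divisible by the number of parameters.
    """
    if not isinstance(rankings, Mapping):
        rankings = {r.parameter: r for r in rankings}
    n_par = len(rankings)
    if n_par == 0 or ns % n_par != 0:
        raise ValueError(f"ns={ns} must be divisible by {n_par} parameters")
    model_id = model_id or next(iter(rankings.values())).model_id
    ordered = {p: r.ordered_features for p, r in rankings.items()}
    cursors = {p: 0 for p in ordered}
    selected: List[str] = []
    chosen: set = set()
    credit: Dict[str, List[str]] = {p: [] for p in ordered}
    while len(selected) < ns:
        progressed = False
        for p in ordered:
            if len(selected) >= ns:
                break
            feats = ordered[p]
            while cursors[p] < len(feats) and feats[cursors[p]] in chosen:
                cursors[p] += 1
            if cursors[p] >= len(feats):
                continue
            name = feats[cursors[p]]
            cursors[p] += 1
            selected.append(name)
            chosen.add(name)
            credit[p].append(name)
            progressed = True
        if not progressed:
            raise ValueError(
                f"fewer than ns={ns} distinct features available")
    return Selection(model_id=model_id, selected=selected, per_parameter=credit)


def summarize_selection(selection: Selection) -> pd.DataFrame:
    """Count selected statistics by (type, direction) per parameter.

    Reproduces the bookkeeping of which kinds of summary statistics —
    spatially-averaged vs topological, computed in x vs y — inform each
    parameter.  Counts sum to ``len(selection.selected)``.
    """
    if not selection.selected:
        raise ValueError("empty selection")
    rows = []
    for param, feats in selection.per_parameter.items():
        counts = {("spatial", "x"): 0, ("spatial", "y"): 0,
                  ("topological", "x"): 0, ("topological", "y"): 0}
        for f in feats:
            counts[(feature_type(f), feature_direction(f))] += 1
        for (t, d), c in counts.items():
            rows.append({"parameter": param, "type": t, "direction": d,
                         "count": c})
    return pd.DataFrame(rows)


def rank_all(
    train: TrainingSet,
    *,
    n_trees: int = 500,
    seed: int = 0,
) -> Dict[str, FeatureRanking]:
    """One ranking per parameter of the training set's model."""
    out = {}
    for k, p in enumerate(PARAM_NAMES[train.model_id]):
        out[p] = rank_features(train, p, n_trees=n_trees, seed=seed + k)
    return out
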