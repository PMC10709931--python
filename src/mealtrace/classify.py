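"""Binary candidate classifiers and per-participant model selection.

Six stock classifier families are trained on the candidate feature table
with library-default hyperparameters (each serves only as a replaceable
tool in the pipeline; no tuning).  Models are then compared on the
validation split with *event-level* scores — predictions are matched to
logged meals within the success margin, not row-by-row — and the model
with the highest F2 (recall-weighted) is selected for the participant.
Ties break on F1, then on the fixed name order below.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .evaluate import MetricsReport, f_beta, match_events, report_from_counts
from .features import FEATURE_NAMES, TrainingTable
from .selection import Candidate, with_prediction

logger = logging.getLogger(__name__)

#: Fixed roster (and tie-break order) of classifier types.
CLASSIFIER_NAMES = (
    "AdaBoost",
    "DecisionTree",
    "GradientBoosting",
    "GaussianNB",
    "MLP",
    "RandomForest",
)


def _make_estimator(name: str, seed: int):
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    if name == "DecisionTree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "GradientBoosting":
        return GradientBoostingClassifier(random_state=seed)
    if name == "GaussianNB":
        return GaussianNB()
    if name == "MLP":
        return MLPClassifier(random_state=seed)
    if name == "RandomForest":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class TrainedModel:
    classifier_name: str
    estimator: object
    seed: int
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=bool)


@dataclass
class ModelSelectionReport:
    per_model: dict[str, MetricsReport]
    selected: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in sorted(
            self.per_model.items(), key=lambda kv: -kv[1].f2
        ):
            rows.append(
                {
                    "classifier": name,
                    "meals": r.counts.meals,
                    "predictions": r.counts.predictions,
                    "fp": r.counts.fp,
                    "fn": r.counts.fn,
                    "tp": r.counts.tp,
                    "ppv": r.ppv,
                    "tpr": r.tpr,
                    "f1": r.f1,
                    "f2": r.f2,
                }
            )
        return pd.DataFrame(rows)


def train_all(table: TrainingTable, seed: int = 0) -> list[TrainedModel]:
    """Fit all six classifier types on the training table.

    Stochastic estimators are seeded for reproducibility; hyperparameters
    are library defaults and are echoed to the log.
    """
    if len(table) == 0:
        raise ValueError("empty training table")
    n_pos = int(table.y.sum())
    n_neg = int(len(table) - n_pos)
    if n_pos == 0 or n_neg == 0:
        missing = "Meal" if n_pos == 0 else "NonMeal"
        raise ValueError(f"training table has no {missing} rows; cannot fit")
    models = []
    for name in CLASSIFIER_NAMES:
        est = _make_estimator(name, seed)
        logger.info("fitting %s with params %s", name, est.get_params())
        with warnings.catch_warnings():
            # MLP at default max_iter may stop before full convergence;
            # that is part of the default-hyperparameter contract
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(table.X, table.y)
        models.append(TrainedModel(classifier_name=name, estimator=est, seed=seed))
    return models


def evaluate_model_events(
    model: TrainedModel,
    cands: Sequence[Candidate],
    meal_times: Sequence[pd.Timestamp],
    delta_margin: pd.Timedelta,
) -> tuple[list[Candidate], MetricsReport]:
    """Predict on featurized candidates and score at the event level."""
    if cands:
        X = np.vstack([c.features for c in cands])
        preds = model.predict(X)
    else:
        preds = np.array([], dtype=bool)
    predicted = [with_prediction(c, bool(p)) for c, p in zip(cands, preds)]
    pred_times = [c.start_time for c in predicted if c.prediction]
    _, counts = match_events(pred_times, list(meal_times), delta_margin)
    return predicted, report_from_counts(counts, scope="split-pooled")


def select_model(
    models: Sequence[TrainedModel],
    cands: Sequence[Candidate],
    meal_times: Sequence[pd.Timestamp],
    delta_margin: pd.Timedelta,
) -> ModelSelectionReport:
    """Pick the per-participant model by validation F2.

    Ties resolve to the higher F1, then to the fixed roster order, and the
    rule is recorded here so the winner is independent of input order.
    """
    if not meal_times:
        raise ValueError("validation split contains no meal events")
    per_model: dict[str, MetricsReport] = {}
    for model in models:
        _, report = evaluate_model_events(model, cands, meal_times, delta_margin)
        per_model[model.classifier_name] = report
    roster = {name: i for i, name in enumerate(CLASSIFIER_NAMES)}
    selected = min(
        per_model,
        key=lambda name: (-per_model[name].f2, -per_model[name].f1, roster.get(name, 99)),
    )
    return ModelSelectionReport(per_model=per_model, selected=selected)


__all__ = [
    "CLASSIFIER_NAMES",
    "TrainedModel",
    "ModelSelectionReport",
    "train_all",
    "evaluate_model_events",
    "select_model",
    "f_beta",
]
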