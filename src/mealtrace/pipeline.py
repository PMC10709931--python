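"""End-to-end orchestration: train (patterns -> profiles -> candidates ->
table -> models -> selection), detect on held-out data, evaluate.

The data are split by time into train / validation / test; patterns are
identified on the training span only, the per-participant classifier is
chosen by event-level F2 on validation, and detection applies the frozen
patterns and the selected model to the test span.  Every stage works on
its own time slice, so no stage sees data outside its declared split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from .classify import ModelSelectionReport, TrainedModel, select_model, train_all
from .core import (
    CGMError,
    DataSplit,
    EventLog,
    GlucoseSeries,
    split_data,
    synchronize_events,
)
from .features import (
    TrainingTable,
    build_training_table,
    featurize_candidates,
    label_candidates,
)
from .patterns import (
    ResponsePattern,
    SelectionParams,
    extract_meal_responses,
    identify_patterns,
)
from .profiles import DistanceProfile, compute_profiles
from .selection import Candidate, select_candidates, with_prediction
from .simulate import SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one train/detect run."""

    selection: SelectionParams = field(default_factory=SelectionParams)
    simulation: Optional[SimulationConfig] = None
    test_span: pd.Timedelta = pd.Timedelta(days=7)
    seed: int = 0


@dataclass
class TrainArtifacts:
    split: DataSplit
    patterns: list[ResponsePattern]
    train_profiles: list[DistanceProfile]
    train_candidates: list[Candidate]
    table: TrainingTable
    models: list[TrainedModel]
    selection_report: ModelSelectionReport

    @property
    def selected_model(self) -> TrainedModel:
        return next(
            m for m in self.models
            if m.classifier_name == self.selection_report.selected
        )


@dataclass
class DetectionResult:
    candidates: list[Candidate]  # with predictions attached
    predicted_times: list[pd.Timestamp]
    daily: list[ev.MetricsReport]
    pooled: ev.MetricsReport
    macro: Optional[ev.MetricsReport]


def _candidates_for_span(
    T: GlucoseSeries,
    patterns: Sequence[ResponsePattern],
    params: SelectionParams,
) -> list[Candidate]:
    """Profiles + selection + featurization for one time slice; an all-gap
    slice yields no candidates."""
    try:
        profiles = compute_profiles(T, list(patterns))
    except ValueError as exc:
        logger.warning("no usable signal in span: %s", exc)
        return []
    cands = select_candidates(profiles, params, T.interval, T.time_at)
    return featurize_candidates(T, cands, params.delta_response)


def run_train(T: GlucoseSeries, E: EventLog, cfg: RunConfig) -> TrainArtifacts:
    """Execute the training pipeline on the train span and pick the
    per-participant model on the validation span."""
    split = split_data(T, E, cfg.test_span)
    T_tr, E_tr = split.train
    E_tr = synchronize_events(T_tr, E_tr)
    if len(E_tr) == 0:
        raise ValueError("pattern stage: no meal events in the training span")

    responses = extract_meal_responses(T_tr, E_tr, cfg.selection.delta_response)
    patterns = identify_patterns(responses, cfg.selection.n_patterns, seed=cfg.seed)
    train_profiles = compute_profiles(T_tr, patterns)
    train_cands = select_candidates(
        train_profiles, cfg.selection, T_tr.interval, T_tr.time_at
    )
    train_cands = featurize_candidates(T_tr, train_cands, cfg.selection.delta_response)
    train_cands = label_candidates(
        train_cands, E_tr, cfg.selection.delta_margin, T_tr
    )
    table = build_training_table(
        T_tr, E_tr, train_cands, cfg.selection.delta_response, cfg.selection.delta_margin
    )
    models = train_all(table, seed=cfg.seed)

    T_val, E_val = split.validation
    if T_val is None:
        raise ValueError("model selection requires a non-empty validation span")
    E_val = synchronize_events(T_val, E_val)
    val_cands = _candidates_for_span(T_val, patterns, cfg.selection)
    meal_times = [T_val.time_at(ev_.grid_index) for ev_ in E_val]
    report = select_model(models, val_cands, meal_times, cfg.selection.delta_margin)
    logger.info("selected %s by validation F2", report.selected)
    return TrainArtifacts(
        split=split,
        patterns=patterns,
        train_profiles=train_profiles,
        train_candidates=train_cands,
        table=table,
        models=models,
        selection_report=report,
    )


def run_detect(
    T: GlucoseSeries,
    E: EventLog,
    patterns: Sequence[ResponsePattern],
    model: TrainedModel,
    params: SelectionParams,
) -> DetectionResult:
    """Apply frozen patterns + selected model to a held-out span and score
    the predicted meal times against the logged events."""
    try:
        E_sync = synchronize_events(T, E)
        meal_times = [T.time_at(ev_.grid_index) for ev_ in E_sync]
    except CGMError:
        # a reading-free span still owes its meals as false negatives
        meal_times = [ev_.time for ev_ in E]
    cands = _candidates_for_span(T, patterns, params)
    if cands:
        X = np.vstack([c.features for c in cands])
        preds = model.predict(X)
        cands = [with_prediction(c, bool(p)) for c, p in zip(cands, preds)]
    pred_times = [c.start_time for c in cands if c.prediction]

    daily = ev.daily_reports(pred_times, meal_times, params.delta_margin)
    if daily:
        pooled = ev.aggregate(daily, "pooled")
        macro = ev.aggregate(daily, "macro")
    else:
        pooled = ev.report_from_counts(
            ev.ConfusionCounts(0, 0, 0, 0, 0), scope="split-pooled"
        )
        macro = None
    return DetectionResult(
        candidates=cands,
        predicted_times=pred_times,
        daily=daily,
        pooled=pooled,
        macro=macro,
    )


def run_end_to_end(
    T: GlucoseSeries, E: EventLog, cfg: RunConfig
) -> tuple[TrainArtifacts, DetectionResult]:
    """Train, select, and detect on the final held-out test span."""
    art = run_train(T, E, cfg)
    T_test, E_test = art.split.test
    if T_test is None:
        raise ValueError("no test span configured")
    det = run_detect(T_test, E_test, art.patterns, art.selected_model, cfg.selection)
    return art, det


# ---------------------------------------------------------------------------
# Artifact persistence (JSON/CSV; used by the command-line layer)


def save_patterns(patterns: Sequence[ResponsePattern], path: Path) -> None:
    payload = [
        {
            "pattern_id": p.pattern_id,
            "values": [float(v) for v in p.values],
            "provenance": list(p.provenance),
        }
        for p in patterns
    ]
    path.write_text(json.dumps(payload, indent=2))


def load_patterns(path: Path) -> list[ResponsePattern]:
    payload = json.loads(path.read_text())
    return [
        ResponsePattern(
            pattern_id=d["pattern_id"],
            values=np.asarray(d["values"]),
            provenance=tuple(d["provenance"]),
        )
        for d in payload
    ]


def save_profiles(profiles: Sequence[DistanceProfile], path: Path) -> None:
    payload = {
        str(d.pattern_id): [
            None if not np.isfinite(v) else float(v) for v in d.values
        ]
        for d in profiles
    }
    path.write_text(json.dumps(payload))


def candidates_frame(cands: Sequence[Candidate]) -> pd.DataFrame:
    def fmt(flag: Optional[bool]) -> str:
        if flag is None:
            return ""
        return "Meal" if flag else "NonMeal"

    return pd.DataFrame(
        {
            "start_time": [c.start_time for c in cands],
            "pattern_id": [c.pattern_id for c in cands],
            "distance": [c.distance for c in cands],
            "label": [fmt(c.label) for c in cands],
            "prediction": [fmt(c.prediction) for c in cands],
        }
    )
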