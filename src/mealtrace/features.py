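"""Candidate featurization, margin labeling and training-table assembly.

Each candidate is summarized by nine qualitative variables computed from
its response window alone (no event information leaks into features):

========================  =========================================  =========
feature                   description                                unit
========================  =========================================  =========
bg                        glucose at the window start                mg/dl
bg_derivative             forward difference over one grid step      mg/dl/min
elapsed_hours             hours since local midnight at the start    hours
resp_min                  minimum glucose in the window              mg/dl
resp_minutes_to_min       minutes from start to that minimum         minutes
resp_deriv_to_min         (min - bg) / minutes_to_min (0 at start)   mg/dl/min
resp_max                  maximum glucose in the window              mg/dl
resp_minutes_to_max       minutes from start to that maximum         minutes
resp_deriv_to_max         (max - bg) / minutes_to_max (0 at start)   mg/dl/min
========================  =========================================  =========

A candidate is labeled *Meal* when its start lies within the closed
interval ``[t - delta_margin, t + delta_margin]`` of some logged meal at
``t``; otherwise *Non-Meal*.  The training table holds all labeled
candidates plus one extra positive row per logged meal that was matched by
at least one Meal candidate (featurized at the meal's own grid index);
*dangling* meals — matched by no candidate — contribute no row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import EventLog, GlucoseSeries, subsequence_at
from .selection import Candidate

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "bg",
    "bg_derivative",
    "elapsed_hours",
    "resp_min",
    "resp_minutes_to_min",
    "resp_deriv_to_min",
    "resp_max",
    "resp_minutes_to_max",
    "resp_deriv_to_max",
)


def compute_features(
    T: GlucoseSeries, start_index: int, delta_response: pd.Timedelta
) -> np.ndarray:
    """Feature vector (order of :data:`FEATURE_NAMES`) for the response
    window starting at ``start_index``.  The window must be gap-free."""
    n = int(round(delta_response / T.interval))
    sub = subsequence_at(T, start_index, n)
    if sub is None:
        raise ValueError(f"window at index {start_index} crosses a gap")
    x = sub.values
    step_min = T.interval.total_seconds() / 60.0
    bg = x[0]
    bg_deriv = (x[1] - x[0]) / step_min
    ts = sub.start_time
    elapsed_hours = (ts - ts.normalize()).total_seconds() / 3600.0
    i_min = int(np.argmin(x))  # first occurrence on ties
    i_max = int(np.argmax(x))
    min_minutes = i_min * step_min
    max_minutes = i_max * step_min
    deriv_min = (x[i_min] - bg) / min_minutes if min_minutes > 0 else 0.0
    deriv_max = (x[i_max] - bg) / max_minutes if max_minutes > 0 else 0.0
    return np.array(
        [
            bg,
            bg_deriv,
            elapsed_hours,
            x[i_min],
            min_minutes,
            deriv_min,
            x[i_max],
            max_minutes,
            deriv_max,
        ]
    )


def _event_time(T: GlucoseSeries, ev) -> pd.Timestamp:
    """A synchronized event's position on the grid."""
    if ev.grid_index is None:
        raise ValueError("events must be synchronized before labeling")
    return T.time_at(ev.grid_index)


def label_candidates(
    cands: list[Candidate],
    E: EventLog,
    delta_margin: pd.Timedelta,
    T: GlucoseSeries,
) -> list[Candidate]:
    """Label each candidate Meal iff it starts within ``delta_margin``
    (closed interval) of some synchronized meal event."""
    meal_times = [_event_time(T, ev) for ev in E]
    out = []
    for c in cands:
        is_meal = any(abs(c.start_time - t) <= delta_margin for t in meal_times)
        out.append(replace(c, label=is_meal))
    return out


@dataclass(frozen=True)
class TrainingTable:
    """Feature rows with binary labels and provenance."""

    X: np.ndarray  # (rows, 9)
    y: np.ndarray  # bool, True = Meal
    provenance: tuple[str, ...]  # "candidate" | "logged_meal"

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df["label"] = np.where(self.y, "Meal", "NonMeal")
        df["provenance"] = list(self.provenance)
        return df


def build_training_table(
    T: GlucoseSeries,
    E: EventLog,
    labeled: list[Candidate],
    delta_response: pd.Timedelta,
    delta_margin: pd.Timedelta,
) -> TrainingTable:
    """Assemble candidate rows plus matched-meal augmentation rows.

    A logged meal is *matched* when at least one Meal-labeled candidate
    starts within ``delta_margin`` of it; each matched meal contributes at
    most one extra positive row, featurized at the meal's own grid index
    (skipped when that window crosses a gap).  Dangling meals add nothing.
    """
    rows, labels, prov = [], [], []
    for c in labeled:
        feats = (
            c.features
            if c.features is not None
            else compute_features(T, c.start_index, delta_response)
        )
        rows.append(feats)
        labels.append(bool(c.label))
        prov.append("candidate")

    meal_cands = [c for c in labeled if c.label]
    n = int(round(delta_response / T.interval))
    skipped = 0
    for ev in E:
        t = _event_time(T, ev)
        matched = any(abs(c.start_time - t) <= delta_margin for c in meal_cands)
        if not matched:
            continue  # dangling meal: no candidate supports it
        if ev.grid_index > T.m - n or subsequence_at(T, ev.grid_index, n) is None:
            skipped += 1
            continue
        rows.append(compute_features(T, ev.grid_index, delta_response))
        labels.append(True)
        prov.append("logged_meal")
    if skipped:
        logger.info("skipped %d matched-meal augmentation rows (gapped windows)", skipped)
    X = np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
    return TrainingTable(X=X, y=np.array(labels, dtype=bool), provenance=tuple(prov))


def featurize_candidates(
    T: GlucoseSeries, cands: list[Candidate], delta_response: pd.Timedelta
) -> list[Candidate]:
    """Attach feature vectors to candidates (windows are gap-free by
    selection)."""
    return [
        replace(c, features=compute_features(T, c.start_index, delta_response))
        for c in cands
    ]
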