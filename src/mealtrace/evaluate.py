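"""Event-level evaluation: margin matching, confusion counts, F-beta.

Predictions are matched to logged meals one-to-one: candidate pairs with
|dt| <= delta_margin are accepted greedily in ascending |dt| (ties toward
the earlier prediction, then the earlier meal).  Matched pairs are true
positives, unmatched predictions false positives, unmatched meals false
negatives — so the identities tp + fp = predictions and tp + fn = meals
hold by construction.

Two aggregation modes over per-day results are provided: *pooled* (sum the
counts, then compute metrics) and *macro* (arithmetic mean of the per-day
counts and of the per-day metrics).  They genuinely differ whenever days
are unbalanced, so reports are explicitly labeled with their scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    meals: float
    predictions: float
    tp: float
    fp: float
    fn: float

    def __post_init__(self):
        if min(self.meals, self.predictions, self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    ppv: float
    tpr: float
    f1: float
    f2: float
    scope: str  # "day" | "split-pooled" | "split-macro"
    day: str | None = None


def f_beta(tp: float, fp: float, fn: float, beta: float) -> float:
    """F-beta from confusion counts.

    ``(1 + beta^2) * PPV * TPR / (beta^2 * PPV + TPR)``; beta > 1 weights
    recall over precision.  With tp = 0 the score is 0 by convention
    (PPV/TPR undefined or zero); all-zero counts are an error.
    """
    if tp + fp + fn <= 0:
        raise ValueError("at least one of tp, fp, fn must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if tp == 0:
        return 0.0
    ppv = tp / (tp + fp)
    tpr = tp / (tp + fn)
    b2 = beta * beta
    return (1 + b2) * ppv * tpr / (b2 * ppv + tpr)


def precision_recall(tp: float, fp: float, fn: float) -> tuple[float, float]:
    ppv = tp / (tp + fp) if tp + fp > 0 else 0.0
    tpr = tp / (tp + fn) if tp + fn > 0 else 0.0
    return ppv, tpr


def match_events(
    pred_times: Sequence[pd.Timestamp],
    meal_times: Sequence[pd.Timestamp],
    delta_margin: pd.Timedelta,
) -> tuple[list[tuple[int, int]], ConfusionCounts]:
    """Greedy one-to-one nearest-time matching within ``delta_margin``.

    Returns the matched (prediction index, meal index) pairs and the
    confusion counts they imply.
    """
    pairs = []
    for i, tp_ in enumerate(pred_times):
        for j, tm in enumerate(meal_times):
            dt = abs(tp_ - tm)
            if dt <= delta_margin:
                pairs.append((dt, i, j))
    pairs.sort(key=lambda x: (x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_m: set[int] = set()
    matching = []
    for _, i, j in pairs:
        if i in used_p or j in used_m:
            continue
        used_p.add(i)
        used_m.add(j)
        matching.append((i, j))
    tp = len(matching)
    counts = ConfusionCounts(
        meals=len(meal_times),
        predictions=len(pred_times),
        tp=tp,
        fp=len(pred_times) - tp,
        fn=len(meal_times) - tp,
    )
    return matching, counts


def report_from_counts(
    counts: ConfusionCounts, scope: str, day: str | None = None
) -> MetricsReport:
    if counts.tp + counts.fp + counts.fn <= 0:
        ppv = tpr = f1 = f2 = 0.0
    else:
        ppv, tpr = precision_recall(counts.tp, counts.fp, counts.fn)
        f1 = f_beta(counts.tp, counts.fp, counts.fn, beta=1)
        f2 = f_beta(counts.tp, counts.fp, counts.fn, beta=2)
    return MetricsReport(counts, ppv, tpr, f1, f2, scope=scope, day=day)


def daily_reports(
    pred_times: Sequence[pd.Timestamp],
    meal_times: Sequence[pd.Timestamp],
    delta_margin: pd.Timedelta,
) -> list[MetricsReport]:
    """Independent evaluation per calendar day (local midnight boundary).

    Days carrying neither meals nor predictions are omitted.
    """
    days = sorted(
        {t.normalize() for t in pred_times} | {t.normalize() for t in meal_times}
    )
    out = []
    for day in days:
        p = [t for t in pred_times if t.normalize() == day]
        e = [t for t in meal_times if t.normalize() == day]
        _, counts = match_events(p, e, delta_margin)
        out.append(report_from_counts(counts, scope="day", day=str(day.date())))
    return out


def aggregate(reports: Sequence[MetricsReport], mode: str) -> MetricsReport:
    """Combine per-day reports.

    ``pooled``: sum counts across days, recompute metrics from the sums.
    ``macro``: arithmetic mean of per-day counts and of per-day metrics.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    if mode == "pooled":
        counts = ConfusionCounts(
            meals=sum(r.counts.meals for r in reports),
            predictions=sum(r.counts.predictions for r in reports),
            tp=sum(r.counts.tp for r in reports),
            fp=sum(r.counts.fp for r in reports),
            fn=sum(r.counts.fn for r in reports),
        )
        return report_from_counts(counts, scope="split-pooled")
    if mode == "macro":
        k = len(reports)
        counts = ConfusionCounts(
            meals=sum(r.counts.meals for r in reports) / k,
            predictions=sum(r.counts.predictions for r in reports) / k,
            tp=sum(r.counts.tp for r in reports) / k,
            fp=sum(r.counts.fp for r in reports) / k,
            fn=sum(r.counts.fn for r in reports) / k,
        )
        return MetricsReport(
            counts,
            ppv=sum(r.ppv for r in reports) / k,
            tpr=sum(r.tpr for r in reports) / k,
            f1=sum(r.f1 for r in reports) / k,
            f2=sum(r.f2 for r in reports) / k,
            scope="split-macro",
        )
    raise ValueError(f"unknown aggregation mode {mode!r}")


def report_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Tabular view mirroring the standard column layout."""
    return pd.DataFrame(
        {
            "day": [r.day for r in reports],
            "meals": [r.counts.meals for r in reports],
            "predictions": [r.counts.predictions for r in reports],
            "fp": [r.counts.fp for r in reports],
            "fn": [r.counts.fn for r in reports],
            "tp": [r.counts.tp for r in reports],
            "ppv": [r.ppv for r in reports],
            "tpr": [r.tpr for r in reports],
            "f1": [r.f1 for r in reports],
            "f2": [r.f2 for r in reports],
        }
    )
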