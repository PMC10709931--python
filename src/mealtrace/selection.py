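"""Candidate selection from distance profiles.

The selection procedure turns each pattern's distance profile into a
dynamic number of meal-response candidates:

1. *Valley picking* (per pattern): local minima of the profile below the
   similarity cutoff ``d_cutoff`` are taken greedily in ascending distance
   order while suppressing any remaining minimum closer than the valley
   width ``delta_valley`` to an already-selected one.  This keeps only the
   most similar occurrence in each neighbourhood.
2. *Global grouping* (across patterns): surviving candidates are clustered
   on their start times (1-D agglomerative, average linkage) with the
   dendrogram cut at ``delta_valley``; each temporal cluster contributes
   exactly its minimum-distance member.

A static top-n selection per pattern is provided as the comparison
baseline the dynamic procedure improves on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .patterns import SelectionParams
from .profiles import DistanceProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Candidate:
    """A possible meal-response start position."""

    start_index: int
    start_time: pd.Timestamp
    pattern_id: int
    distance: float
    features: Optional[np.ndarray] = None
    label: Optional[bool] = None  # True = Meal
    prediction: Optional[bool] = None


def _local_minima(values: np.ndarray) -> list[int]:
    """Indices of strict local minima; a flat plateau lower than both of
    its differing neighbours yields its leftmost index.  Boundary positions
    (including segment boundaries created by +inf sentinels) count when
    lower than their single inner neighbour."""
    minima = []
    L = len(values)
    j = 0
    while j < L:
        v = values[j]
        if not np.isfinite(v):
            j += 1
            continue
        # extend over a plateau of equal values
        k = j
        while k + 1 < L and values[k + 1] == v:
            k += 1
        left_ok = j == 0 or not np.isfinite(values[j - 1]) or values[j - 1] > v
        right_ok = k == L - 1 or not np.isfinite(values[k + 1]) or values[k + 1] > v
        if left_ok and right_ok:
            minima.append(j)  # leftmost index of the plateau
        j = k + 1
    return minima


def get_valleys(
    d: DistanceProfile,
    d_cutoff: float,
    valley_samples: int,
    time_at=None,
) -> list[Candidate]:
    """Valley minima of one profile below ``d_cutoff`` with greedy
    suppression at ``valley_samples`` spacing.

    Minima are visited in ascending distance (ties toward the earlier
    position); a minimum strictly closer than ``valley_samples`` to an
    already-selected one is suppressed, so selected positions end up at
    least ``valley_samples`` apart.  Output is sorted by time.
    """
    minima = [j for j in _local_minima(d.values) if d.values[j] < d_cutoff]
    order = sorted(minima, key=lambda j: (d.values[j], j))
    selected: list[int] = []
    for j in order:
        if all(abs(j - s) >= valley_samples for s in selected):
            selected.append(j)
    selected.sort()
    return [
        Candidate(
            start_index=j,
            start_time=time_at(j) if time_at else pd.Timestamp(0),
            pattern_id=d.pattern_id,
            distance=float(d.values[j]),
        )
        for j in selected
    ]


def group_candidates(
    cands: list[Candidate], delta_valley: pd.Timedelta
) -> list[Candidate]:
    """Merge candidates close in time across patterns; keep one per group.

    1-D agglomerative clustering (average linkage) on start times with the
    dendrogram cut at ``delta_valley``; each cluster is represented by its
    minimum-distance candidate (ties: earliest time, then lowest
    pattern_id).
    """
    if len(cands) <= 1:
        return list(cands)
    cands = sorted(cands, key=lambda c: (c.start_time, c.pattern_id))
    t_min = np.array(
        [(c.start_time - cands[0].start_time).total_seconds() / 60.0 for c in cands]
    )
    Z = linkage(t_min.reshape(-1, 1), method="average")
    labels = fcluster(Z, t=delta_valley.total_seconds() / 60.0, criterion="distance")
    out = []
    for lab in np.unique(labels):
        members = [c for c, g in zip(cands, labels) if g == lab]
        best = min(members, key=lambda c: (c.distance, c.start_time, c.pattern_id))
        out.append(best)
    out.sort(key=lambda c: c.start_time)
    return out


def select_candidates(
    profiles: list[DistanceProfile],
    params: SelectionParams,
    interval: pd.Timedelta,
    time_at,
) -> list[Candidate]:
    """Full selection: per-pattern valleys, then global temporal grouping.

    Gap-crossing windows carry +inf in the profiles and can never be
    selected; this is asserted here as the contiguity guarantee.
    """
    w = int(round(params.delta_valley / interval))
    pooled: list[Candidate] = []
    for d in profiles:
        pooled.extend(get_valleys(d, params.d_cutoff, w, time_at=time_at))
    if not pooled:
        logger.warning("no profile value below d_cutoff=%s anywhere", params.d_cutoff)
        return []
    assert all(np.isfinite(c.distance) for c in pooled)
    pooled.sort(key=lambda c: (c.start_time, c.pattern_id))
    return group_candidates(pooled, params.delta_valley)


def top_n_select(
    profiles: list[DistanceProfile], n_top: int, time_at
) -> list[Candidate]:
    """Static baseline: the n_top smallest finite profile values per
    pattern, with no suppression or grouping."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    out: list[Candidate] = []
    for d in profiles:
        finite = np.flatnonzero(d.finite_mask)
        order = finite[np.lexsort((finite, d.values[finite]))]
        for j in order[:n_top]:
            out.append(
                Candidate(
                    start_index=int(j),
                    start_time=time_at(int(j)),
                    pattern_id=d.pattern_id,
                    distance=float(d.values[j]),
                )
            )
    out.sort(key=lambda c: (c.start_time, c.pattern_id))
    return out


def with_prediction(c: Candidate, pred: bool) -> Candidate:
    return replace(c, prediction=pred)
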