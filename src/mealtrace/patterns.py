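"""Meal-response extraction and response-pattern identification.

A *meal response* is the fixed-length contiguous glucose window starting at
a logged meal's grid position.  Responses are z-normalized to shapes and
clustered (agglomerative, average linkage, Euclidean) into a small number
of *response patterns*; each pattern is its cluster's medoid, so every
pattern is a shape actually observed in the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import EventLog, GlucoseSeries, Subsequence, subsequence_at

logger = logging.getLogger(__name__)

#: Standard deviations below this are treated as zero (constant window).
ZNORM_EPS = 1e-8


@dataclass(frozen=True)
class SelectionParams:
    """Tunable parameters of the candidate-selection method.

    Defaults are the method's reference operating point for 5-minute CGM:
    a 2-hour response window (n = 24 samples), a 1-hour success margin for
    matching candidates/predictions to logged meals, 3 patterns, a z-norm
    distance cutoff of 4, and a 2-hour valley / grouping scale.
    """

    delta_response: pd.Timedelta = pd.Timedelta(hours=2)
    delta_margin: pd.Timedelta = pd.Timedelta(hours=1)
    n_patterns: int = 3
    d_cutoff: float = 4.0
    delta_valley: pd.Timedelta = pd.Timedelta(hours=2)

    def __post_init__(self):
        if self.n_patterns < 1 or self.d_cutoff <= 0:
            raise ValueError("n_patterns and d_cutoff must be positive")
        for td in (self.delta_response, self.delta_margin, self.delta_valley):
            if td <= pd.Timedelta(0):
                raise ValueError("durations must be positive")

    def window_samples(self, interval: pd.Timedelta) -> int:
        n = self.delta_response / interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("delta_response must be a multiple of the grid interval")
        return int(round(n))


@dataclass(frozen=True)
class ResponsePattern:
    """A z-normalized archetypal meal-response shape used as a search query."""

    pattern_id: int
    values: np.ndarray  # z-normalized, length n
    provenance: tuple[int, ...] = ()  # indices of the responses in its cluster


def extract_meal_responses(
    T: GlucoseSeries, E: EventLog, delta_response: pd.Timedelta
) -> list[Subsequence]:
    """One fixed-length window per synchronized event, starting at the
    event's grid index.

    Windows that would run past the series end or straddle a gap are
    skipped (their count is logged): the method only trains on contiguous
    responses.
    """
    n = int(round(delta_response / T.interval))
    out, skipped = [], 0
    for ev in E:
        if ev.grid_index is None:
            raise ValueError("events must be synchronized before extraction")
        if ev.grid_index > T.m - n:
            skipped += 1
            continue
        sub = subsequence_at(T, ev.grid_index, n)
        if sub is None:
            skipped += 1
            continue
        out.append(sub)
    if skipped:
        logger.info("skipped %d/%d meal responses (gaps or series end)", skipped, len(E))
    return out


def znormalize(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return ``((x - mean)/sd, degenerate)``.

    A window whose sd is below :data:`ZNORM_EPS` carries no shape; it maps
    to all-zeros with the degenerate flag set.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to z-normalize")
    sd = float(x.std())
    if sd < ZNORM_EPS:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def identify_patterns(
    responses: list[Subsequence], n_patterns: int, seed: int = 0
) -> list[ResponsePattern]:
    """Cluster z-normalized responses and return one medoid per cluster.

    Agglomerative clustering with average linkage on Euclidean distances
    between shapes; the medoid (minimal summed distance to its cluster) is
    returned so each pattern is a real observed response.  Deterministic
    given the input order; ``seed`` is accepted for interface uniformity.
    """
    shapes, keep = [], []
    for idx, r in enumerate(responses):
        z, degenerate = znormalize(r.values)
        if degenerate:
            logger.info("dropping constant response at index %d", idx)
            continue
        shapes.append(z)
        keep.append(idx)
    if len(shapes) < n_patterns:
        raise ValueError(
            f"only {len(shapes)} usable responses for {n_patterns} patterns; "
            "reduce n_patterns or provide more events"
        )
    X = np.vstack(shapes)
    if n_patterns == len(shapes):
        labels = np.arange(len(shapes))
    else:
        from sklearn.cluster import AgglomerativeClustering

        labels = AgglomerativeClustering(
            n_clusters=n_patterns, linkage="average", metric="euclidean"
        ).fit_predict(X)

    dmat = squareform(pdist(X))
    patterns = []
    # order clusters by first appearance so pattern ids are stable
    seen: list[int] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    for pid, lab in enumerate(seen):
        members = np.flatnonzero(labels == lab)
        medoid = members[int(np.argmin(dmat[np.ix_(members, members)].sum(axis=1)))]
        patterns.append(
            ResponsePattern(
                pattern_id=pid,
                values=X[medoid].copy(),
                provenance=tuple(int(keep[i]) for i in members),
            )
        )
    if len({p.values.tobytes() for p in patterns}) < len(patterns):
        logger.info("identical patterns found; downstream grouping will deduplicate")
    return patterns
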