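"""Core domain types for per-participant CGM data.

A participant is described by the tuple ``X = (T, E, P, D)``: the gridded
blood-glucose series ``T``, the logged meal-event series ``E``, a set of
identified response patterns ``P`` and the corresponding distance profiles
``D``.  This module provides ``T`` and ``E`` (with grid/gap handling, event
synchronization and time-based splitting); patterns and profiles live in
:mod:`mealtrace.patterns` and :mod:`mealtrace.profiles`.

Conventions
-----------
* The glucose signal lives on a regular grid (default 5 minutes) anchored at
  the first reading; a *gap* is a grid position with no reading, stored as
  NaN.  Indices are 0-based and windows ``[i, i+n-1]`` are inclusive of both
  ends (length ``n``).
* Glucose is in mg/dl and must be finite and strictly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed set of event types carried by the self-reported log.
EVENT_TYPES = ("breakfast", "lunch", "dinner", "snack", "hypo_correction")

DEFAULT_INTERVAL = pd.Timedelta(minutes=5)


class CGMError(Exception):
    """Base error for malformed or inconsistent CGM inputs."""


class ParseError(CGMError):
    """A CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class GlucoseSeries:
    """A blood-glucose signal on a regular time grid, gaps included.

    ``values[j]`` is the reading at ``start + j * interval`` or NaN when the
    sensor produced nothing for that grid position.
    """

    participant_id: str
    start: pd.Timestamp
    interval: pd.Timedelta
    values: np.ndarray  # float array of length m, NaN marks a gap

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite <= 0).any():
            raise CGMError("glucose values must be > 0 mg/dl")

    @property
    def m(self) -> int:
        """Number of grid positions spanned, missing ones included."""
        return len(self.values)

    @property
    def end(self) -> pd.Timestamp:
        """Exclusive end of the covered time range."""
        return self.start + self.m * self.interval

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.m, freq=self.interval)

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of grid positions that hold a reading."""
        return np.isfinite(self.values)

    def is_gap(self, i: int) -> bool:
        return not np.isfinite(self.values[i])

    def index_of(self, ts: pd.Timestamp) -> float:
        """Fractional grid index of a timestamp (may be off-grid)."""
        return (ts - self.start) / self.interval

    def time_at(self, i: int) -> pd.Timestamp:
        return self.start + i * self.interval

    def slice(self, lo: int, hi: int) -> "GlucoseSeries":
        """Sub-series over grid positions ``[lo, hi)``."""
        if not (0 <= lo <= hi <= self.m):
            raise IndexError(f"slice [{lo}, {hi}) out of range for m={self.m}")
        return replace(self, start=self.time_at(lo), values=self.values[lo:hi])

    @classmethod
    def from_samples(
        cls,
        timestamps: Sequence[pd.Timestamp],
        glucose: Sequence[float],
        participant_id: str = "",
        interval: pd.Timedelta = DEFAULT_INTERVAL,
    ) -> "GlucoseSeries":
        """Build a gridded series from (timestamp, value) samples.

        Timestamps must be strictly increasing.  Readings off the grid
        anchored at the first timestamp are snapped to the nearest grid
        position; when two readings snap to the same position the first wins.
        """
        ts = pd.DatetimeIndex(timestamps)
        if len(ts) == 0:
            raise CGMError("empty glucose series")
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            raise CGMError("timestamps must be strictly increasing")
        idx = np.round((ts - ts[0]) / interval).astype(int)
        m = int(idx[-1]) + 1
        values = np.full(m, np.nan)
        for j, g in zip(idx, glucose):
            if np.isnan(values[j]):  # duplicate snaps keep the first
                values[j] = g
        return cls(participant_id, ts[0], interval, values)


@dataclass(frozen=True)
class MealEvent:
    time: pd.Timestamp
    event_type: str
    grid_index: Optional[int] = None  # set by synchronize_events

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise CGMError(
                f"unknown event type {self.event_type!r}; expected one of {EVENT_TYPES}"
            )


@dataclass(frozen=True)
class EventLog:
    """Ordered self-reported meal events."""

    entries: tuple[MealEvent, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        times = [e.time for e in self.entries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise CGMError("event timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[MealEvent]:
        return iter(self.entries)

    @property
    def times(self) -> list[pd.Timestamp]:
        return [e.time for e in self.entries]


@dataclass(frozen=True)
class Subsequence:
    """A contiguous gap-free window ``[i, i+n-1]`` of the glucose signal."""

    start_index: int
    start_time: pd.Timestamp
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class ParticipantData:
    """The participant tuple ``X = (T, E, P, D)``; ``P``/``D`` start empty."""

    id: str
    T: GlucoseSeries
    E: EventLog
    P: list = field(default_factory=list)
    D: list = field(default_factory=list)


@dataclass(frozen=True)
class DataSplit:
    """Contiguous, ordered train < validation < test partition of (T, E)."""

    train: tuple[GlucoseSeries, EventLog]
    validation: tuple[Optional[GlucoseSeries], EventLog]
    test: tuple[Optional[GlucoseSeries], EventLog]


# ---------------------------------------------------------------------------
# I/O


def read_glucose_csv(
    path: Path | str,
    participant_id: str = "",
    interval: pd.Timedelta = DEFAULT_INTERVAL,
) -> GlucoseSeries:
    """Read a ``timestamp,glucose_mg_dl`` CSV into a gridded series."""
    path = Path(path)
    timestamps, glucose = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",")[:2] != ["timestamp", "glucose_mg_dl"]:
            raise ParseError(f"unexpected header {header!r}", line=1)
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split(",")
            if len(parts) != 2:
                raise ParseError(f"expected 2 fields, got {len(parts)}", line=lineno)
            try:
                ts = pd.Timestamp(parts[0])
                g = float(parts[1])
            except (ValueError, TypeError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if not np.isfinite(g) or g <= 0:
                raise ParseError(f"glucose {g} out of range (must be > 0)", line=lineno)
            timestamps.append(ts)
            glucose.append(g)
    if not timestamps:
        raise ParseError("no data rows", line=2)
    return GlucoseSeries.from_samples(timestamps, glucose, participant_id, interval)


def write_glucose_csv(T: GlucoseSeries, path: Path | str) -> None:
    mask = T.present
    df = pd.DataFrame(
        {"timestamp": T.timestamps[mask], "glucose_mg_dl": T.values[mask]}
    )
    df.to_csv(path, index=False)


def read_events_csv(path: Path | str) -> EventLog:
    """Read a ``timestamp,event_type`` CSV into an :class:`EventLog`."""
    path = Path(path)
    entries = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",")[:2] != ["timestamp", "event_type"]:
            raise ParseError(f"unexpected header {header!r}", line=1)
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split(",")
            if len(parts) != 2:
                raise ParseError(f"expected 2 fields, got {len(parts)}", line=lineno)
            try:
                entries.append(MealEvent(pd.Timestamp(parts[0]), parts[1]))
            except (ValueError, CGMError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return EventLog(tuple(entries))


def write_events_csv(E: EventLog, path: Path | str) -> None:
    df = pd.DataFrame(
        {"timestamp": [e.time for e in E], "event_type": [e.event_type for e in E]}
    )
    df.to_csv(path, index=False)


def read_participant(
    cgm_path: Path | str,
    events_path: Path | str,
    participant_id: str = "",
    interval: pd.Timedelta = DEFAULT_INTERVAL,
) -> ParticipantData:
    """Load the (T, E) part of a participant tuple; patterns start empty."""
    T = read_glucose_csv(cgm_path, participant_id, interval)
    E = read_events_csv(events_path)
    return ParticipantData(id=participant_id, T=T, E=E)


# ---------------------------------------------------------------------------
# Operations


def synchronize_events(T: GlucoseSeries, E: EventLog) -> EventLog:
    """Assign each event the grid index of the nearest *existing* reading.

    Equidistant neighbours resolve to the earlier reading.  Events falling
    outside the series' covered range by more than one interval are dropped
    with a warning.
    """
    if T.m == 0:
        raise CGMError("cannot synchronize against an empty series")
    present_idx = np.flatnonzero(T.present)
    if present_idx.size == 0:
        raise CGMError("series has no readings")
    present_times = T.start.value + present_idx * T.interval.value
    kept = []
    for ev in E:
        if (ev.time < T.start - T.interval) or (ev.time > T.end + T.interval):
            logger.warning(
                "event %s at %s outside series span; dropped", ev.event_type, ev.time
            )
            continue
        deltas = np.abs(present_times - ev.time.value)
        # ties toward the earlier point: argmin returns the first minimum
        j = int(present_idx[int(np.argmin(deltas))])
        kept.append(MealEvent(ev.time, ev.event_type, grid_index=j))
    return EventLog(tuple(kept))


def split_data(T: GlucoseSeries, E: EventLog, test_span: pd.Timedelta) -> DataSplit:
    """Split by time span: test = final ``test_span``, validation = the span
    immediately before it, train = everything earlier.

    Validation and test cover equal spans, mirroring a ~50-25-25 layout when
    ``test_span`` is a quarter of the data.
    """
    n_test = int(round(test_span / T.interval))
    if n_test < 0:
        raise ValueError("test_span must be non-negative")
    total_span = T.m * T.interval
    if n_test > 0 and total_span <= 2 * test_span:
        raise ValueError(
            f"total span {total_span} too short for two {test_span} holdouts"
        )
    b1 = T.m - 2 * n_test  # train | validation boundary
    b2 = T.m - n_test  # validation | test boundary
    t1, t2 = T.time_at(b1), T.time_at(b2)

    def bucket(parts):
        return EventLog(tuple(parts))

    ev_train, ev_val, ev_test = [], [], []
    for ev in E:
        if ev.time < t1:
            ev_train.append(ev)
        elif ev.time < t2:
            ev_val.append(ev)
        else:
            ev_test.append(ev)
    return DataSplit(
        train=(T.slice(0, b1), bucket(ev_train)),
        validation=(T.slice(b1, b2) if n_test else None, bucket(ev_val)),
        test=(T.slice(b2, T.m) if n_test else None, bucket(ev_test)),
    )


def subsequence_at(T: GlucoseSeries, i: int, n: int) -> Optional[Subsequence]:
    """Window ``[i, i+n-1]`` of ``T``, or None (gap flag) if any position in
    it is missing."""
    if not (0 <= i <= T.m - n) or n < 1:
        raise IndexError(f"window [{i}, {i + n - 1}] out of range for m={T.m}")
    window = T.values[i : i + n]
    if not np.isfinite(window).all():
        return None
    return Subsequence(start_index=i, start_time=T.time_at(i), values=window.copy())
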