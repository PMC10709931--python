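"""Z-normalized Euclidean distance profiles (MASS).

For a query pattern ``p`` of length ``n`` and a glucose series spanning
``m`` grid positions, the distance profile is the vector of z-normalized
Euclidean distances between ``p`` and every length-``n`` subsequence of the
series — the similarity search primitive behind candidate selection.

Two routes are provided: :func:`distance_profile`, the FFT-accelerated
MASS computation used by the pipeline, and :func:`brute_force_profile`, a
direct O(m*n) evaluation kept as an independent oracle.  Positions whose
window crosses a gap, runs past a contiguous segment, or has zero variance
receive a ``+inf`` sentinel; all finite values lie in ``[0, 2*sqrt(n)]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core import GlucoseSeries
from .patterns import ZNORM_EPS, ResponsePattern, znormalize


@dataclass(frozen=True)
class DistanceProfile:
    pattern_id: int
    n: int  # query length, samples
    values: np.ndarray  # length m - n + 1; +inf marks unusable positions

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def _contiguous_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) runs of True in a boolean mask."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def _mass_segment(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    """MASS on one gap-free segment ``x`` against z-normalized query ``q``.

    With the query z-normalized (sum 0, sum of squares n), the squared
    z-normalized distance at offset j reduces to ``2n - 2 * dot_j / sd_j``
    where ``dot_j`` is the sliding dot product and ``sd_j`` the window's
    population standard deviation.  The sliding dot product is computed by
    FFT convolution with the reversed query.
    """
    n = len(q)
    L = len(x)
    dot = fftconvolve(x, q[::-1], mode="valid")  # length L - n + 1
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    win_sum = csum[n:] - csum[:-n]
    win_sum2 = csum2[n:] - csum2[:-n]
    mean = win_sum / n
    var = np.maximum(win_sum2 / n - mean * mean, 0.0)
    sd = np.sqrt(var)
    out = np.full(L - n + 1, np.inf)
    ok = sd >= ZNORM_EPS
    d2 = 2.0 * n - 2.0 * dot[ok] / sd[ok]
    out[ok] = np.sqrt(np.maximum(d2, 0.0))
    return out


def distance_profile(T: GlucoseSeries, p: ResponsePattern) -> DistanceProfile:
    """FFT-accelerated profile of ``p`` against every subsequence of ``T``.

    Computed per contiguous gap-free segment and stitched with ``+inf``
    sentinels, so windows that would straddle a gap are excluded upstream
    of candidate selection.
    """
    n = len(p.values)
    if n < 2:
        raise ValueError("pattern length must be >= 2")
    segments = [(a, b) for a, b in _contiguous_segments(T.present) if b - a >= n]
    if not segments:
        raise ValueError(
            f"no contiguous gap-free segment of length >= {n} in the series"
        )
    values = np.full(max(T.m - n + 1, 0), np.inf)
    q = p.values.astype(float)
    for a, b in segments:
        values[a : b - n + 1] = _mass_segment(T.values[a:b], q)
    return DistanceProfile(pattern_id=p.pattern_id, n=n, values=values)


def brute_force_profile(T: GlucoseSeries, p: ResponsePattern) -> DistanceProfile:
    """Direct O(m*n) oracle: z-normalize every window and take the
    Euclidean distance to the z-normalized pattern."""
    n = len(p.values)
    if n < 2:
        raise ValueError("pattern length must be >= 2")
    q = p.values.astype(float)
    m = T.m
    values = np.full(max(m - n + 1, 0), np.inf)
    any_segment = False
    for j in range(m - n + 1):
        window = T.values[j : j + n]
        if not np.isfinite(window).all():
            continue
        any_segment = True
        z, degenerate = znormalize(window)
        if degenerate:
            continue
        values[j] = float(np.linalg.norm(z - q))
    if not any_segment:
        raise ValueError(
            f"no contiguous gap-free segment of length >= {n} in the series"
        )
    return DistanceProfile(pattern_id=p.pattern_id, n=n, values=values)


def compute_profiles(
    T: GlucoseSeries, patterns: list[ResponsePattern]
) -> list[DistanceProfile]:
    """One distance profile per pattern (the participant tuple's ``D``)."""
    return [distance_profile(T, p) for p in patterns]
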