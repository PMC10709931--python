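"""Seeded synthetic CGM generator.

Emulates the data regime the detection method assumes: a 5-minute blood
glucose grid carrying a slow circadian baseline plus Gaussian sensor noise,
additive meal responses drawn from a small library of distinct kernel
shapes, sensor dropout in contiguous runs, and an imperfect self-reported
meal log (missed entries, timestamp jitter).

The signal model is deliberately additive, not physiological: the detection
method only assumes that meals produce recurring response *shapes*, so the
simplest generator exposing that structure is used.  What passing tests on
this generator do and do not imply about real sensor data is discussed in
the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EventLog, GlucoseSeries, MealEvent

#: Sensor reporting range, mg/dl (typical CGM hardware clamp).
CLIP_LO, CLIP_HI = 40.0, 400.0

#: Kernels are truncated to zero beyond this horizon (minutes).
KERNEL_HORIZON_MIN = 240.0


@dataclass(frozen=True)
class ResponseKernel:
    """One archetypal post-meal glucose excursion shape.

    The shape rises smoothly from 0 to ``amplitude`` at ``time_to_peak``
    minutes, then decays exponentially with half-life ``decay_half_life``.
    An optional pre-rise dip (a half-sine notch of ``dip_depth`` mg/dl over
    the first ``dip_minutes``) models the early insulin-driven drop some
    responses show; when used the rise starts after the dip.
    """

    amplitude: float  # mg/dl, > 0
    time_to_peak: float  # minutes, > 0
    decay_half_life: float  # minutes, > 0
    dip_depth: float = 0.0  # mg/dl, >= 0
    dip_minutes: float = 0.0  # minutes; must be < time_to_peak when dip_depth > 0

    def __post_init__(self):
        if self.amplitude <= 0 or self.time_to_peak <= 0 or self.decay_half_life <= 0:
            raise ValueError("amplitude, time_to_peak and decay_half_life must be > 0")
        if self.dip_depth > 0 and not (0 < self.dip_minutes < self.time_to_peak):
            raise ValueError("dip_minutes must lie strictly before time_to_peak")


def kernel_value(k: ResponseKernel, minutes_since_meal: float) -> float:
    """Kernel height (mg/dl) at ``minutes_since_meal``.

    0 at t = 0, ``amplitude`` at the peak, half the amplitude one decay
    half-life past the peak, and identically 0 beyond the 4-hour horizon.
    """
    t = minutes_since_meal
    if t < 0:
        raise ValueError("time since meal must be >= 0")
    if t == 0 or t >= KERNEL_HORIZON_MIN:
        return 0.0
    if k.dip_depth > 0 and t < k.dip_minutes:
        # dip phase: half-sine notch, 0 at both ends
        return -k.dip_depth * math.sin(math.pi * t / k.dip_minutes)
    rise_start = k.dip_minutes if k.dip_depth > 0 else 0.0
    if t <= k.time_to_peak:
        frac = (t - rise_start) / (k.time_to_peak - rise_start)
        return k.amplitude * math.sin(0.5 * math.pi * frac) ** 2
    v = k.amplitude * 2.0 ** (-(t - k.time_to_peak) / k.decay_half_life)
    # cosine taper over the final quarter of the horizon so the kernel
    # reaches exactly zero without a step in the simulated signal
    taper_start = 0.75 * KERNEL_HORIZON_MIN
    if t > taper_start:
        v *= 0.5 * (1.0 + math.cos(math.pi * (t - taper_start) / (0.25 * KERNEL_HORIZON_MIN)))
    return v


def default_kernel_library() -> list[ResponseKernel]:
    """Three distinct shapes: sharp/high, dipped/medium, slow/flat.

    Matching the default pattern-set size |P| = 3; the shapes are chosen so
    their pairwise z-normalized distances comfortably exceed within-shape
    noise at the default noise level (separability is asserted by tests).
    """
    return [
        # fast spike: quickly absorbed carbohydrates
        ResponseKernel(amplitude=80.0, time_to_peak=30.0, decay_half_life=25.0),
        # mixed meal with an early insulin-driven dip before the rise
        ResponseKernel(
            amplitude=60.0, time_to_peak=80.0, decay_half_life=50.0,
            dip_depth=30.0, dip_minutes=35.0,
        ),
        # slow, late-peaking response (fat/protein-heavy meal)
        ResponseKernel(amplitude=45.0, time_to_peak=125.0, decay_half_life=50.0),
    ]


#: (clock window start hour, end hour, probability of occurring, kernel idx,
#:  event type)
DEFAULT_MEAL_SCHEDULE = [
    (6.5, 8.5, 0.95, 0, "breakfast"),
    (11.5, 13.5, 0.95, 1, "lunch"),
    (15.0, 16.5, 0.30, 2, "snack"),
    (17.5, 19.5, 0.95, 2, "dinner"),
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated participant.

    Defaults describe a 28-day adult wearing a 5-minute CGM: baseline around
    120 mg/dl with a +-10 mg/dl circadian swing, 5 mg/dl sensor noise, three
    meal-response shapes, 2% of samples lost in contiguous dropout runs, and
    a faithful log (no missed entries) with 5-minute reporting jitter.
    """

    n_days: int = 28
    interval_minutes: float = 5.0
    baseline_mean: float = 120.0  # mg/dl
    baseline_amplitude: float = 10.0  # mg/dl, circadian sinusoid
    drift_sd: float = 15.0  # mg/dl, stationary sd of the slow baseline wander
    drift_tau_hours: float = 3.0  # correlation time of the wander
    noise_sd: float = 5.0  # mg/dl
    kernel_library: list[ResponseKernel] = field(default_factory=default_kernel_library)
    meal_schedule: list[tuple] = field(
        default_factory=lambda: list(DEFAULT_MEAL_SCHEDULE)
    )
    gap_rate: float = 0.02  # fraction of samples removed, in runs
    mean_gap_run: float = 6.0  # mean dropout run length, samples
    miss_log_prob: float = 0.0  # P(true meal absent from the log)
    log_jitter_sd: float = 5.0  # minutes
    start: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2022-03-01"))
    participant_id: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p in (self.gap_rate, self.miss_log_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def simulate_participant(
    cfg: SimulationConfig,
) -> tuple[GlucoseSeries, EventLog, EventLog]:
    """Simulate one participant; returns ``(T, E_true, E_logged)``.

    ``T`` is baseline + sum of kernel responses + Gaussian noise, clipped to
    the sensor range and with dropout runs removed.  ``E_true`` holds the
    exact meal times; ``E_logged`` is the imperfect self-report (entries
    missing with probability ``miss_log_prob``, timestamps jittered).
    """
    rng = np.random.default_rng(cfg.seed)
    interval = pd.Timedelta(minutes=cfg.interval_minutes)
    m = int(round(cfg.n_days * 24 * 60 / cfg.interval_minutes))
    minutes = np.arange(m) * cfg.interval_minutes
    hour_of_day = (minutes / 60.0) % 24.0

    signal = cfg.baseline_mean + cfg.baseline_amplitude * np.sin(
        2 * math.pi * (hour_of_day - 4.0) / 24.0
    )

    # slow mean-reverting baseline wander (insulin sensitivity, stress,
    # activity ... everything non-meal that moves the baseline): an
    # Ornstein-Uhlenbeck walk with stationary sd drift_sd
    if cfg.drift_sd > 0:
        rho = math.exp(-cfg.interval_minutes / (cfg.drift_tau_hours * 60.0))
        innov_sd = cfg.drift_sd * math.sqrt(1.0 - rho * rho)
        drift = np.empty(m)
        drift[0] = rng.normal(0.0, cfg.drift_sd)
        shocks = rng.normal(0.0, innov_sd, size=m)
        for j in range(1, m):
            drift[j] = rho * drift[j - 1] + shocks[j]
        signal += drift

    # draw true meals day by day from the clock-time schedule
    meals: list[tuple[float, int, str]] = []  # (minute offset, kernel idx, type)
    for day in range(cfg.n_days):
        for lo, hi, prob, k_idx, etype in cfg.meal_schedule:
            if rng.random() < prob:
                t_min = (day * 24 + rng.uniform(lo, hi)) * 60.0
                meals.append((t_min, k_idx, etype))
    meals.sort(key=lambda x: x[0])

    for t_meal, k_idx, _ in meals:
        kern = cfg.kernel_library[k_idx]
        j0 = int(math.ceil(t_meal / cfg.interval_minutes))
        j1 = min(m, int(math.ceil((t_meal + KERNEL_HORIZON_MIN) / cfg.interval_minutes)))
        for j in range(max(j0, 0), j1):
            signal[j] += kernel_value(kern, minutes[j] - t_meal)

    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=m)
    signal = np.clip(signal, CLIP_LO, CLIP_HI)

    # contiguous dropout runs until the target fraction is reached
    if cfg.gap_rate > 0:
        target = int(round(cfg.gap_rate * m))
        removed = np.zeros(m, dtype=bool)
        while removed.sum() < target:
            run = int(rng.geometric(1.0 / cfg.mean_gap_run))
            j = int(rng.integers(0, m))
            removed[j : j + run] = True
        signal[removed] = np.nan

    T = GlucoseSeries(cfg.participant_id, cfg.start, interval, signal)

    true_entries = [
        MealEvent(cfg.start + pd.Timedelta(minutes=t), etype)
        for t, _, etype in meals
    ]
    logged_entries = []
    for ev in true_entries:
        if rng.random() < cfg.miss_log_prob:
            continue
        jitter = rng.normal(0.0, cfg.log_jitter_sd) if cfg.log_jitter_sd > 0 else 0.0
        logged_entries.append(
            MealEvent(ev.time + pd.Timedelta(minutes=float(jitter)), ev.event_type)
        )
    logged_entries.sort(key=lambda e: e.time)
    return T, EventLog(tuple(true_entries)), EventLog(tuple(logged_entries))
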