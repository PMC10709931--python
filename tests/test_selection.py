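"""Candidate selection: valley picking, temporal grouping, top-n baseline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mealtrace import (
    SelectionParams,
    SimulationConfig,
    get_valleys,
    group_candidates,
    select_candidates,
    simulate_participant,
    synchronize_events,
    top_n_select,
)
from mealtrace.profiles import DistanceProfile, compute_profiles
from mealtrace.patterns import extract_meal_responses, identify_patterns
from mealtrace.selection import Candidate

from conftest import T0, FIVE_MIN


def profile(values, pid=0, n=2):
    return DistanceProfile(pattern_id=pid, n=n, values=np.asarray(values, float))


def time_at(j):
    return T0 + j * FIVE_MIN


def cand(minutes, distance, pid=0):
    return Candidate(
        start_index=minutes // 5,
        start_time=T0 + pd.Timedelta(minutes=minutes),
        pattern_id=pid,
        distance=distance,
    )


class TestGetValleys:
    def test_greedy_valley_example(self):
        d = profile([5, 3.5, 3.2, 5, 5, 3.0, 5])
        out = get_valleys(d, d_cutoff=4, valley_samples=2, time_at=time_at)
        assert [(c.start_index, c.distance) for c in out] == [(2, 3.2), (5, 3.0)]

    def test_all_above_cutoff_empty(self):
        d = profile([5, 4.5, 4.0, 6])
        assert get_valleys(d, 4, 2, time_at=time_at) == []

    def test_single_minimum(self):
        d = profile([5, 3.0, 5])
        out = get_valleys(d, 4, 2, time_at=time_at)
        assert [c.start_index for c in out] == [1]

    def test_plateau_takes_leftmost(self):
        d = profile([5, 3.0, 3.0, 5, 5, 5, 5, 5, 5, 5, 5, 2.0, 5])
        out = get_valleys(d, 4, 3, time_at=time_at)
        assert [c.start_index for c in out] == [1, 11]

    def test_inf_sentinels_segment_boundaries(self):
        d = profile([np.inf, 3.0, 5, np.inf, np.inf, 2.0, np.inf])
        out = get_valleys(d, 4, 2, time_at=time_at)
        assert [c.start_index for c in out] == [1, 5]

    @given(st.integers(min_value=0, max_value=10_000))
    def test_suppression_spacing_and_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        d = profile(rng.uniform(1, 8, size=60))
        w = int(rng.integers(1, 30))
        out = get_valleys(d, 4.0, w, time_at=time_at)
        assert all(c.distance < 4.0 for c in out)
        idx = [c.start_index for c in out]
        assert all(
            abs(a - b) >= w for i, a in enumerate(idx) for b in idx[i + 1 :]
        )
        times = [c.start_time for c in out]
        assert times == sorted(times)


class TestGrouping:
    def test_two_cluster_example(self):
        cands = [
            cand(8 * 60, 3.1, pid=0),
            cand(8 * 60 + 30, 2.8, pid=1),
            cand(13 * 60, 3.5, pid=0),
        ]
        out = group_candidates(cands, pd.Timedelta(hours=2))
        assert [(c.start_time, c.distance) for c in out] == [
            (T0 + pd.Timedelta(hours=8, minutes=30), 2.8),
            (T0 + pd.Timedelta(hours=13), 3.5),
        ]

    def test_single_candidate(self):
        c = cand(100, 3.0)
        assert group_candidates([c], pd.Timedelta(hours=2)) == [c]

    def test_no_merging_when_far_apart(self):
        cands = [cand(0, 3.0), cand(3 * 60, 2.0), cand(7 * 60, 3.9)]
        out = group_candidates(cands, pd.Timedelta(hours=2))
        assert out == cands

    def test_tie_breaks_earlier_then_pattern(self):
        a = cand(60, 3.0, pid=1)
        b = cand(90, 3.0, pid=0)
        out = group_candidates([a, b], pd.Timedelta(hours=2))
        assert out == [a]

    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_subset_of_input(self, seed):
        rng = np.random.default_rng(seed)
        cands = [
            cand(int(t), float(d), pid=int(p))
            for t, d, p in zip(
                np.sort(rng.integers(0, 24 * 60, size=12)),
                rng.uniform(1, 4, size=12),
                rng.integers(0, 3, size=12),
            )
        ]
        out = group_candidates(cands, pd.Timedelta(hours=2))
        assert len(out) <= len(cands)
        assert all(c in cands for c in out)


class TestSelectCandidates:
    def test_single_pattern_reduces_to_valleys(self):
        d = profile([5, 3.5, 3.2, 5, 5, 3.0, 5])
        params = SelectionParams(delta_valley=pd.Timedelta(minutes=10))
        out = select_candidates([d], params, FIVE_MIN, time_at)
        valleys = get_valleys(d, params.d_cutoff, 2, time_at=time_at)
        assert [(c.start_index, c.distance) for c in out] == [
            (c.start_index, c.distance) for c in valleys
        ]

    def test_two_patterns_one_meal_one_survivor(self):
        # both patterns dip at nearly the same position: one representative
        d0 = profile([6, 5, 3.0, 5, 6, 6, 6, 6, 6, 6], pid=0)
        d1 = profile([6, 6, 5, 2.5, 5, 6, 6, 6, 6, 6], pid=1)
        params = SelectionParams(delta_valley=pd.Timedelta(minutes=20))
        out = select_candidates([d0, d1], params, FIVE_MIN, time_at)
        assert len(out) == 1
        assert out[0].pattern_id == 1 and out[0].distance == 2.5

    def test_nothing_below_cutoff_warns_and_returns_empty(self, caplog):
        d = profile([6.0, 5.5, 6.0])
        with caplog.at_level("WARNING"):
            out = select_candidates([d], SelectionParams(), FIVE_MIN, time_at)
        assert out == []
        assert "d_cutoff" in caplog.text

    def test_synthetic_meals_are_covered(self):
        """With one meal per valley window and clean patterns, selection
        places a candidate within the success margin of >= 80% of meals."""
        cfg = SimulationConfig(
            n_days=10,
            seed=3,
            gap_rate=0.0,
            miss_log_prob=0.0,
            log_jitter_sd=0.0,
            meal_schedule=[
                (7.0, 8.0, 1.0, 0, "breakfast"),
                (12.0, 13.0, 1.0, 1, "lunch"),
                (18.0, 19.0, 1.0, 2, "dinner"),
            ],
        )
        T, e_true, _ = simulate_participant(cfg)
        E = synchronize_events(T, e_true)
        params = SelectionParams()
        responses = extract_meal_responses(T, E, params.delta_response)
        patterns = identify_patterns(responses, params.n_patterns)
        cands = select_candidates(
            compute_profiles(T, patterns), params, T.interval, T.time_at
        )
        margin = params.delta_margin
        covered = sum(
            any(abs(c.start_time - ev.time) <= margin for c in cands) for ev in e_true
        )
        assert covered >= 0.8 * len(e_true)


class TestTopN:
    def test_global_minimum_per_pattern(self):
        d0 = profile([5, 3.5, 3.2, 5], pid=0)
        d1 = profile([2.0, 5, 5, 5], pid=1)
        out = top_n_select([d0, d1], 1, time_at)
        assert {(c.pattern_id, c.start_index) for c in out} == {(0, 2), (1, 0)}

    def test_sorting_example(self):
        d = profile([5, 3.5, 3.2, 5, 5, 3.0, 5])
        out = top_n_select([d], 2, time_at)
        assert sorted(c.start_index for c in out) == [2, 5]

    def test_n_exceeding_positions_returns_all_finite(self):
        d = profile([5, 3.5, np.inf, 5])
        out = top_n_select([d], 100, time_at)
        assert len(out) == 3

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_n_select([profile([1.0, 2.0])], 0, time_at)
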