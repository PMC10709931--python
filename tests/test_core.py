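"""Grid/gap handling, event synchronization and time-based splitting."""

import numpy as np
import pandas as pd
import pytest

from mealtrace import (
    EventLog,
    MealEvent,
    split_data,
    subsequence_at,
    synchronize_events,
)
from mealtrace.core import (
    CGMError,
    GlucoseSeries,
    ParseError,
    read_events_csv,
    read_glucose_csv,
    read_participant,
    write_events_csv,
    write_glucose_csv,
)

from conftest import FIVE_MIN, T0, make_series


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReading:
    def test_two_row_file_spans_two_grid_positions(self, tmp_path):
        cgm = write(
            tmp_path,
            "cgm.csv",
            "timestamp,glucose_mg_dl\n2022-03-01 08:00,100\n2022-03-01 08:05,110\n",
        )
        events = write(tmp_path, "ev.csv", "timestamp,event_type\n")
        pdata = read_participant(cgm, events, participant_id="p1")
        assert pdata.T.m == 2
        assert pdata.T.present.all()
        assert len(pdata.E) == 0
        assert pdata.P == [] and pdata.D == []

    def test_grid_arithmetic_inserts_gaps(self, tmp_path):
        cgm = write(
            tmp_path,
            "cgm.csv",
            "timestamp,glucose_mg_dl\n2022-03-01 08:00,100\n2022-03-01 08:15,110\n",
        )
        T = read_glucose_csv(cgm)
        assert T.m == 4
        assert list(T.present) == [True, False, False, True]

    def test_malformed_row_reports_line_number(self, tmp_path):
        cgm = write(
            tmp_path,
            "cgm.csv",
            "timestamp,glucose_mg_dl\n2022-03-01 08:00,100\nnot-a-date,xx\n",
        )
        with pytest.raises(ParseError) as err:
            read_glucose_csv(cgm)
        assert err.value.line == 3

    def test_nonpositive_glucose_rejected(self, tmp_path):
        cgm = write(
            tmp_path, "cgm.csv", "timestamp,glucose_mg_dl\n2022-03-01 08:00,-5\n"
        )
        with pytest.raises(ParseError):
            read_glucose_csv(cgm)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        cgm = write(
            tmp_path,
            "cgm.csv",
            "timestamp,glucose_mg_dl\n2022-03-01 08:05,100\n2022-03-01 08:00,110\n",
        )
        with pytest.raises(CGMError):
            read_glucose_csv(cgm)

    def test_roundtrip_preserves_timestamps_and_values(self, tmp_path):
        values = [100.0, np.nan, 117.5, 123.25, np.nan, 99.0]
        T = make_series(values)
        path = tmp_path / "out.csv"
        write_glucose_csv(T, path)
        back = read_glucose_csv(path, participant_id="p1")
        assert back.m == T.m
        np.testing.assert_array_equal(back.values, T.values)
        assert (back.timestamps == T.timestamps).all()

        E = EventLog(
            (
                MealEvent(T0 + pd.Timedelta(hours=8), "breakfast"),
                MealEvent(T0 + pd.Timedelta(hours=12, minutes=3), "lunch"),
            )
        )
        epath = tmp_path / "ev.csv"
        write_events_csv(E, epath)
        eback = read_events_csv(epath)
        assert [e.time for e in eback] == [e.time for e in E]
        assert [e.event_type for e in eback] == [e.event_type for e in E]

    def test_unknown_event_type_rejected(self, tmp_path):
        ev = write(tmp_path, "ev.csv", "timestamp,event_type\n2022-03-01 08:00,brunch\n")
        with pytest.raises(ParseError):
            read_events_csv(ev)


class TestSynchronize:
    def test_exact_hit_keeps_sample_index(self):
        T = make_series([100, 110, 120], start=pd.Timestamp("2022-03-01 08:00"))
        E = EventLog((MealEvent(pd.Timestamp("2022-03-01 08:05"), "lunch"),))
        out = synchronize_events(T, E)
        assert out.entries[0].grid_index == 1

    def test_nearest_point_rule(self):
        T = make_series([100, 110], start=pd.Timestamp("2022-03-01 08:00"))
        E = EventLog((MealEvent(pd.Timestamp("2022-03-01 08:02"), "lunch"),))
        assert synchronize_events(T, E).entries[0].grid_index == 0

    def test_nearest_existing_point_skips_gap(self):
        T = make_series([np.nan, 110], start=pd.Timestamp("2022-03-01 08:00"))
        E = EventLog((MealEvent(pd.Timestamp("2022-03-01 08:02"), "lunch"),))
        assert synchronize_events(T, E).entries[0].grid_index == 1

    def test_equidistant_tie_goes_earlier(self):
        T = make_series([100, 110], start=pd.Timestamp("2022-03-01 08:00"))
        E = EventLog((MealEvent(pd.Timestamp("2022-03-01 08:02:30"), "snack"),))
        assert synchronize_events(T, E).entries[0].grid_index == 0

    def test_far_outside_span_dropped(self, caplog):
        T = make_series([100, 110], start=pd.Timestamp("2022-03-01 08:00"))
        E = EventLog((MealEvent(pd.Timestamp("2022-03-01 09:00"), "dinner"),))
        with caplog.at_level("WARNING"):
            out = synchronize_events(T, E)
        assert len(out) == 0
        assert "dropped" in caplog.text


class TestSplit:
    def _series_days(self, days):
        m = days * 288
        return make_series(100 + np.arange(m) % 50)

    def test_quarters_layout(self):
        T = self._series_days(40)
        split = split_data(T, EventLog(), pd.Timedelta(days=10))
        assert split.train[0].m == 20 * 288
        assert split.validation[0].m == 10 * 288
        assert split.test[0].m == 10 * 288

    def test_zero_test_span_degenerates(self):
        T = self._series_days(4)
        split = split_data(T, EventLog(), pd.Timedelta(0))
        assert split.train[0].m == T.m
        assert split.validation[0] is None and split.test[0] is None

    def test_boundary_arithmetic_12_days(self):
        T = self._series_days(12)
        split = split_data(T, EventLog(), pd.Timedelta(days=3))
        assert split.train[0].start == T0
        assert split.validation[0].start == T0 + pd.Timedelta(days=6)
        assert split.test[0].start == T0 + pd.Timedelta(days=9)
        assert split.test[0].m == 3 * 288

    def test_too_short_raises(self):
        T = self._series_days(5)
        with pytest.raises(ValueError):
            split_data(T, EventLog(), pd.Timedelta(days=3))

    def test_events_partition_exactly_once(self):
        T = self._series_days(12)
        events = tuple(
            MealEvent(T0 + pd.Timedelta(days=d, hours=12), "lunch") for d in range(12)
        )
        split = split_data(T, EventLog(events), pd.Timedelta(days=3))
        parts = [split.train[1], split.validation[1], split.test[1]]
        assert sum(len(p) for p in parts) == len(events)
        assert len(split.train[1]) == 6
        assert len(split.validation[1]) == 3
        assert len(split.test[1]) == 3
        # sample partition: slices tile the grid
        assert (
            split.train[0].m + split.validation[0].m + split.test[0].m == T.m
        )


class TestSubsequence:
    def test_gap_free_window(self):
        T = make_series([100, 105, 110, 115])
        sub = subsequence_at(T, 1, 3)
        np.testing.assert_array_equal(sub.values, [105, 110, 115])
        assert sub.start_time == T0 + FIVE_MIN

    def test_gap_flag(self):
        T = make_series([100, np.nan, 110, 115])
        assert subsequence_at(T, 0, 3) is None

    def test_inclusive_upper_bound(self):
        T = make_series([100, 105, 110, 115])
        sub = subsequence_at(T, 2, 2)
        assert sub is not None and sub.start_index == 2

    def test_out_of_range(self):
        T = make_series([100, 105, 110])
        with pytest.raises(IndexError):
            subsequence_at(T, 2, 2)

    def test_gap_flag_iff_missing_in_window(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(80, 200, size=50)
        vals[rng.choice(50, size=10, replace=False)] = np.nan
        T = make_series(vals)
        n = 6
        for i in range(T.m - n + 1):
            present = np.isfinite(vals[i : i + n]).sum()
            assert (subsequence_at(T, i, n) is None) == (present < n)
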