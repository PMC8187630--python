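"""Alignment rules: windows, bins, previous-night sleep, the 43-column table."""

import logging

import numpy as np
import pandas as pd
import pytest

from pmhm import schema
from pmhm.datatypes import CognitiveSession, SleepEpisode, WearableStream
from pmhm.features import (
    build_feature_table,
    previous_night_sleep,
    read_subject,
    time_of_day_bin,
    window_aggregate,
)
from pmhm.synthetic import SubjectSpec, simulate_subject, write_subject


class TestTimeOfDayBin:
    @pytest.mark.parametrize(
        "clock,expected",
        [
            ("08:00", "bin1"),
            ("10:00", "bin2"),
            ("14:00", "bin3"),  # boundary, left-closed
            ("17:59", "bin3"),
            ("18:00", "bin4"),
            ("23:59", "bin4"),
            ("06:00", "bin1"),
        ],
    )
    def test_bins(self, clock, expected):
        assert time_of_day_bin(pd.Timestamp(f"2023-03-06 {clock}")) == expected

    def test_before_six_logs_and_uses_bin1(self, caplog):
        with caplog.at_level(logging.WARNING, logger="pmhm.features"):
            assert time_of_day_bin(pd.Timestamp("2023-03-06 05:00")) == "bin1"
        assert "before 06:00" in caplog.text


def _stream(channel, minutes, values, anchor="2023-03-06 12:00"):
    t0 = pd.Timestamp(anchor)
    times = np.array(
        [np.datetime64(t0 + pd.Timedelta(minutes=m), "ns") for m in minutes]
    )
    return WearableStream(channel, times, np.asarray(values, dtype=float))


class TestWindowAggregate:
    def test_two_point_mean(self):
        s = _stream("heart_rate", [-10, 10], [60, 80])
        assert window_aggregate(s, "2023-03-06 12:00", (-30, 30), "mean") == 70.0

    def test_empty_window_is_missing(self):
        s = _stream("heart_rate", [-120, 120], [60, 80])
        out = window_aggregate(s, "2023-03-06 12:00", (-30, 30), "mean")
        assert np.isnan(out)

    def test_zero_variance_std(self):
        s = _stream("hrv_sample", [-10, 0, 10], [5, 5, 5])
        assert window_aggregate(s, "2023-03-06 12:00", (-15, 15), "std") == 0.0

    def test_right_open_left_closed(self):
        s = _stream("heart_rate", [-30, 30], [60, 80])
        # -30 included (left-closed), +30 excluded (right-open)
        assert window_aggregate(s, "2023-03-06 12:00", (-30, 30), "mean") == 60.0

    def test_unknown_statistic_rejected(self):
        s = _stream("heart_rate", [0], [60])
        with pytest.raises(ValueError, match="statistic"):
            window_aggregate(s, "2023-03-06 12:00", (-30, 30), "median")

    def test_degenerate_window_rejected(self):
        s = _stream("heart_rate", [0], [60])
        with pytest.raises(ValueError, match="window"):
            window_aggregate(s, "2023-03-06 12:00", (30, -30), "mean")


class TestPreviousNightSleep:
    def test_interval_arithmetic(self):
        ep = SleepEpisode(pd.Timestamp("2023-03-05 23:30"), pd.Timestamp("2023-03-06 07:30"))
        assert previous_night_sleep([ep], pd.Timestamp("2023-03-06 08:00")) == 8.0

    def test_no_episode_within_24h(self):
        ep = SleepEpisode(pd.Timestamp("2023-03-01 23:30"), pd.Timestamp("2023-03-02 07:30"))
        assert np.isnan(previous_night_sleep([ep], pd.Timestamp("2023-03-06 08:00")))

    def test_shared_across_day_emas(self):
        ep = SleepEpisode(pd.Timestamp("2023-03-05 23:00"), pd.Timestamp("2023-03-06 06:30"))
        anchors = [pd.Timestamp(f"2023-03-06 {h}:00") for h in (8, 12, 16, 20)]
        vals = {previous_night_sleep([ep], a) for a in anchors}
        assert vals == {7.5}

    def test_overlapping_episodes_latest_end_wins(self, caplog):
        eps = [
            SleepEpisode(pd.Timestamp("2023-03-05 22:00"), pd.Timestamp("2023-03-06 05:00")),
            SleepEpisode(pd.Timestamp("2023-03-05 23:00"), pd.Timestamp("2023-03-06 07:00")),
        ]
        with caplog.at_level(logging.WARNING, logger="pmhm.features"):
            out = previous_night_sleep(eps, pd.Timestamp("2023-03-06 08:00"))
        assert out == 8.0
        assert "overlapping" in caplog.text


class TestBuildFeatureTable:
    def test_shape_and_order(self, feature_table, complete_subject):
        assert list(feature_table.columns) == list(schema.FEATURES) + [schema.TARGET]
        assert feature_table.shape == (len(complete_subject.ema_records), 44)
        assert feature_table.index.is_monotonic_increasing
        assert not feature_table[schema.TARGET].isna().any()

    def test_nearest_session_tie_goes_earlier(self, complete_subject):
        from pmhm.features import _nearest_session

        sessions = complete_subject.cognitive_sessions  # days 1, 15, 30 at 10:00
        # Exact midpoint between day-1 and day-15 sessions: day 8 10:00.
        tie = sessions[0].timestamp + (sessions[1].timestamp - sessions[0].timestamp) / 2
        assert _nearest_session(sessions, tie).day == 1
        assert _nearest_session(sessions, tie + pd.Timedelta(minutes=1)).day == 15

    def test_session_scalars_constant_between_sessions(self, feature_table):
        # Rows in the first week all map to the day-1 session.
        week1 = feature_table.iloc[: 7 * 4]
        assert week1["gw_consistency"].nunique() == 1

    def test_backward_windows_ignore_future_samples(self, complete_subject):
        """Perturbing wearable samples after an anchor never changes that row."""
        import copy

        base = build_feature_table(complete_subject)
        cutoff = base.index[len(base) // 2]
        mutated = copy.deepcopy(complete_subject)
        for ch, stream in mutated.wearable.items():
            future = stream.times > np.datetime64(cutoff + pd.Timedelta(minutes=30), "ns")
            stream.values[future] = 1e6
        after = build_feature_table(mutated)
        rows = base.index <= cutoff
        pd.testing.assert_frame_equal(base.loc[rows], after.loc[rows])

    def test_watch_off_day_gives_local_missingness(self, complete_subject):
        import copy

        mutated = copy.deepcopy(complete_subject)
        day = pd.Timestamp("2023-03-16")
        for ch, stream in mutated.wearable.items():
            keep = ~(
                (stream.times >= np.datetime64(day, "ns"))
                & (stream.times < np.datetime64(day + pd.Timedelta(days=1), "ns"))
            )
            mutated.wearable[ch] = WearableStream(ch, stream.times[keep], stream.values[keep])
        table = build_feature_table(mutated)
        noon = table.loc[day + pd.Timedelta(hours=12)]
        assert np.isnan(noon["heart_rate"]) and np.isnan(noon["ppg_std"])
        # A day later the +-30 min heart-rate window has data again.
        next_noon = table.loc[day + pd.Timedelta(days=1, hours=12)]
        assert not np.isnan(next_noon["heart_rate"])

    def test_empty_subject_rejected(self, complete_subject):
        import copy

        empty = copy.deepcopy(complete_subject)
        empty.ema_records = []
        with pytest.raises(ValueError, match="EMA"):
            build_feature_table(empty)


class TestDiskRoundTrip:
    def test_write_read_preserves_feature_table(self, tmp_path):
        spec = SubjectSpec(seed=9, n_days=6, completion_prob=1.0)
        subject = simulate_subject(spec)
        direct = build_feature_table(subject)
        write_subject(subject, tmp_path / "S-09")
        loaded = read_subject(tmp_path / "S-09")
        roundtrip = build_feature_table(loaded)
        pd.testing.assert_frame_equal(direct, roundtrip)
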