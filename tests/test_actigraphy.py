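"""Epoch classification, sleep scoring, day segmentation, wear-validity."""

import numpy as np
import pandas as pd
import pytest

from actiprofile import (
    DayRecord,
    IntensityCutpoints,
    RestInterval,
    average_participant,
    classify_intensity,
    detect_rest_intervals,
    process_participant,
    score_sleep,
    segment_days,
    summarize_day,
)
from actiprofile.actigraphy import ActigraphyError, validate_epoch_series


def minute_series(counts, start="2023-01-02 22:00", lux=None, marker=None):
    n = len(counts)
    return pd.DataFrame(
        {
            "timestamp": pd.date_range(start, periods=n, freq="1min"),
            "counts": counts,
            "lux": np.zeros(n) if lux is None else lux,
            "marker": np.zeros(n, dtype=int) if marker is None else marker,
        }
    )


class TestClassifyIntensity:
    @pytest.mark.parametrize(
        "counts, band",
        [
            (0.0, "SB"),          # minimum activity is sedentary
            (178.50, "SB"),       # SB boundary is inclusive
            (178.51, "LPA"),
            (562.49, "LPA"),
            (562.50, "MVPA"),     # MVPA boundary is inclusive
            (5000.0, "MVPA"),
        ],
    )
    def test_cutpoint_boundaries(self, counts, band):
        assert classify_intensity(counts) == band

    def test_total_monotone_partition(self, rng):
        xs = np.sort(rng.uniform(0, 2000, 500))
        bands = classify_intensity(xs)
        order = {"SB": 0, "LPA": 1, "MVPA": 2}
        ranks = [order[b] for b in bands]
        assert ranks == sorted(ranks)  # monotone in counts

    def test_negative_counts_rejected(self):
        with pytest.raises(ActigraphyError):
            classify_intensity(-1.0)


class TestScoreSleep:
    def test_all_quiet_interval_is_full_sleep(self):
        s = minute_series(np.full(480, 5.0))
        iv = RestInterval(s.timestamp.iloc[0], s.timestamp.iloc[-1] + pd.Timedelta(minutes=1))
        asleep, awake = score_sleep(s, iv)
        assert asleep == 480 and awake == 0

    def test_threshold_epoch_counts_as_wake(self):
        s = minute_series([5.0, 20.0, 19.99])
        iv = RestInterval(s.timestamp.iloc[0], s.timestamp.iloc[-1] + pd.Timedelta(minutes=1))
        asleep, awake = score_sleep(s, iv)
        assert asleep == 2 and awake == 1

    def test_injected_waso_excluded_from_sleep(self):
        counts = np.full(480, 5.0)
        counts[200:230] = 50.0  # 30 min of wake after sleep onset
        s = minute_series(counts)
        iv = RestInterval(s.timestamp.iloc[0], s.timestamp.iloc[-1] + pd.Timedelta(minutes=1))
        asleep, awake = score_sleep(s, iv)
        assert asleep == 450 and awake == 30


class TestRestIntervals:
    def test_paired_markers_are_authoritative(self):
        counts = np.concatenate([np.full(480, 5.0), np.full(60, 100.0)])
        marker = np.zeros(540, dtype=int)
        marker[0] = marker[480] = 1
        s = minute_series(counts, marker=marker)
        ivs = detect_rest_intervals(s)
        assert len(ivs) == 1
        assert ivs[0].start == s.timestamp.iloc[0]
        assert ivs[0].end == s.timestamp.iloc[480]

    def test_markerless_night_found_by_heuristic(self):
        # 2 h bright activity, 8 h dark quiet, 2 h bright activity
        counts = np.concatenate([np.full(120, 80.0), np.full(480, 3.0), np.full(120, 80.0)])
        lux = np.concatenate([np.full(120, 300.0), np.full(480, 0.5), np.full(120, 300.0)])
        s = minute_series(counts, start="2023-01-02 20:00", lux=lux)
        ivs = detect_rest_intervals(s)
        assert len(ivs) == 1
        true_start = pd.Timestamp("2023-01-02 22:00")
        assert abs((ivs[0].start - true_start).total_seconds()) <= 600
        assert abs((ivs[0].end - pd.Timestamp("2023-01-03 06:00")).total_seconds()) <= 600

    def test_daytime_only_recording_flags_error(self):
        s = minute_series(np.full(300, 200.0), lux=np.full(300, 400.0))
        with pytest.raises(ActigraphyError, match="no detectable night"):
            detect_rest_intervals(s)


class TestSegmentDays:
    def _iv(self, a, b):
        return RestInterval(pd.Timestamp(a), pd.Timestamp(b))

    def test_bed_to_next_bed_spans_through_24h59(self):
        # bed 22:00, wake 06:00, next bed 23:00: the day's last included
        # minute starts 24 h 59 min after bedtime (the half-open window
        # [bed, next bed) holds epochs 22:00 ... 22:59 the next day)
        ivs = [
            self._iv("2023-01-02 22:00", "2023-01-03 06:00"),
            self._iv("2023-01-03 23:00", "2023-01-04 07:00"),
        ]
        (start, end, night), = segment_days(pd.DataFrame(), ivs)
        last_minute = end - pd.Timedelta(minutes=1)
        assert last_minute - start == pd.Timedelta(hours=24, minutes=59)
        assert night == ivs[0]

    def test_identical_bedtimes_give_1440(self):
        ivs = [
            self._iv("2023-01-02 22:00", "2023-01-03 06:00"),
            self._iv("2023-01-03 22:00", "2023-01-04 06:00"),
        ]
        (start, end, _), = segment_days(pd.DataFrame(), ivs)
        assert (end - start).total_seconds() / 60 == 1440

    def test_single_night_yields_no_day(self):
        ivs = [self._iv("2023-01-02 22:00", "2023-01-03 06:00")]
        assert segment_days(pd.DataFrame(), ivs) == []

    def test_overlapping_intervals_rejected(self):
        ivs = [
            self._iv("2023-01-02 22:00", "2023-01-03 08:00"),
            self._iv("2023-01-03 06:00", "2023-01-03 14:00"),
        ]
        with pytest.raises(ActigraphyError):
            segment_days(pd.DataFrame(), ivs)


class TestSummarizeDay:
    def test_parts_sum_to_window_length(self, epoch_week):
        _, series = epoch_week
        ivs = detect_rest_intervals(series)
        windows = segment_days(series, ivs)
        for i, w in enumerate(windows):
            rec = summarize_day(series, w, index=i)
            assert rec.valid
            assert rec.total_duration == (w[1] - w[0]).total_seconds() / 60

    def test_window_inside_rest_interval_is_pure_sleep(self):
        s = minute_series(np.full(600, 5.0))
        iv = RestInterval(s.timestamp.iloc[0], s.timestamp.iloc[-1] + pd.Timedelta(minutes=1))
        rec = summarize_day(s, (iv.start, iv.start + pd.Timedelta(minutes=300), iv))
        assert rec.sleep == 300 and rec.sb == rec.lpa == rec.mvpa == 0

    def test_round_trip_recovers_generator_targets(self, epoch_week):
        targets, series = epoch_week
        summary, days = process_participant(series)
        assert summary.included and summary.n_days == 7
        assert abs(summary.sleep - targets["sleep"]) <= 2
        assert abs(summary.sb - targets["sb"]) <= 2
        assert abs(summary.lpa - targets["lpa"]) <= 2
        assert abs(summary.mvpa - targets["mvpa"]) <= 2

    def test_waso_credited_to_awake_budget(self):
        from actiprofile import generate_epoch_series

        series = generate_epoch_series(
            {"sleep": 450, "sb": 600, "lpa": 280, "mvpa": 80},
            n_days=5,
            seed=1,
            waso_minutes=30,
        )
        summary, _ = process_participant(series)
        assert summary.included
        assert abs(summary.sleep - 450) <= 2        # WASO never counts as sleep
        assert abs(summary.sb - 630) <= 2           # ...it lands in SB

    def test_validation_rejects_nonuniform_or_negative(self):
        s = minute_series(np.full(10, 5.0))
        bad = s.copy()
        bad.loc[5, "counts"] = -3
        with pytest.raises(ActigraphyError):
            validate_epoch_series(bad)
        gappy = s.drop(index=4)
        with pytest.raises(ActigraphyError):
            validate_epoch_series(gappy)


def day(i, date, sleep=450.0, sb=600.0, lpa=280.0, mvpa=80.0, valid=True):
    return DayRecord(
        index=i, date=pd.Timestamp(date), sleep=sleep, sb=sb, lpa=lpa, mvpa=mvpa, valid=valid
    )


class TestAverageParticipant:
    def test_four_days_excluded_by_wear_rule(self):
        days = [day(i, f"2023-01-0{i+2} 22:00") for i in range(4)]
        summary = average_participant(days)
        assert not summary.included and "4 consecutive" in summary.reason

    def test_five_identical_days_mean_is_the_day(self):
        days = [day(i, f"2023-01-0{i+2} 22:00") for i in range(5)]
        s = average_participant(days)
        assert s.included
        assert (s.sleep, s.sb, s.lpa, s.mvpa) == (450, 600, 280, 80)
        assert s.total_duration == 1410

    def test_mean_is_arithmetic(self):
        sleeps = [440, 450, 460, 450, 450]
        days = [day(i, f"2023-01-0{i+2} 22:00", sleep=s) for i, s in enumerate(sleeps)]
        assert average_participant(days).sleep == 450

    def test_gap_in_days_breaks_consecutive_run(self):
        dates = ["2023-01-02", "2023-01-03", "2023-01-04", "2023-01-08", "2023-01-09"]
        days = [day(i, f"{d} 22:00") for i, d in enumerate(dates)]
        summary = average_participant(days)
        assert not summary.included and summary.n_days == 3
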