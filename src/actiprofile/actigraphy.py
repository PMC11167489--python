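"""Minute-epoch wrist-actigraphy scoring.

Turns an epoch series (timestamp, activity counts/min, lux, event-marker
flag) into bedtime-to-bedtime day records of Sleep, SB, LPA and MVPA
minutes, then participant-level averages.

Scoring rules
-------------
* Awake intensity bands (counts/min): SB ≤ 178.50, LPA 178.51–562.49,
  MVPA ≥ 562.50.
* Sleep inside the nightly rest interval: epochs < 20 counts/min; epochs
  at or above 20 are wake-after-sleep-onset (WASO) and are excluded from
  sleep. WASO minutes are credited to the awake budget via the intensity
  bands (almost always SB), so a day's four parts always sum to its
  window length.
* A "day" runs from one bedtime to the next bedtime, so its duration is
  rarely exactly 1440 min (e.g. bed 22:00, next bed 22:59 → 1499 min).
* Participants need at least 5 calendar-consecutive valid days; the
  longest consecutive run is averaged.

Rest intervals come from paired event-marker presses when available;
otherwise a heuristic picks the longest nightly block of low light and
low movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EPOCH_COLUMNS = ("timestamp", "counts", "lux", "marker")

SB = "SB"
LPA = "LPA"
MVPA = "MVPA"


class ActigraphyError(ValueError):
    """Raised for malformed epoch data."""


@dataclass(frozen=True)
class IntensityCutpoints:
    """Counts/min thresholds for awake intensity bands and sleep/wake."""

    sb_max: float = 178.50
    lpa_min: float = 178.51
    lpa_max: float = 562.49
    mvpa_min: float = 562.50
    sleep_wake: float = 20.0

    def __post_init__(self):
        if not (0 < self.sb_max < self.lpa_min <= self.lpa_max < self.mvpa_min):
            raise ActigraphyError("cutpoints must be ordered sb_max < lpa_min <= lpa_max < mvpa_min")


DEFAULT_CUTPOINTS = IntensityCutpoints()


@dataclass(frozen=True)
class RestInterval:
    """One night's rest window: bedtime to final wake."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        if self.end <= self.start:
            raise ActigraphyError("rest interval end must follow start")


@dataclass
class DayRecord:
    """Minutes per behavior for one bedtime-to-bedtime day."""

    index: int
    date: pd.Timestamp
    sleep: float
    sb: float
    lpa: float
    mvpa: float
    valid: bool = True
    reason: str = ""

    @property
    def total_duration(self) -> float:
        return self.sleep + self.sb + self.lpa + self.mvpa

    def parts(self) -> np.ndarray:
        return np.array([self.sleep, self.sb, self.lpa, self.mvpa])


def validate_epoch_series(series: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, strictly increasing uniform timestamps, counts ≥ 0."""
    missing = set(EPOCH_COLUMNS) - set(series.columns)
    if missing:
        raise ActigraphyError(f"epoch series missing columns: {sorted(missing)}")
    ts = pd.to_datetime(series["timestamp"])
    dt = ts.diff().dropna()
    if len(ts) > 1:
        if (dt <= pd.Timedelta(0)).any():
            raise ActigraphyError("timestamps must be strictly increasing")
        if dt.nunique() > 1:
            raise ActigraphyError("timestamps must be uniformly spaced")
    if (series["counts"] < 0).any():
        raise ActigraphyError("negative activity counts")
    out = series.copy()
    out["timestamp"] = ts
    return out


def load_epoch_series(path) -> pd.DataFrame:
    """Read an epoch CSV (timestamp ISO-8601, counts, lux, marker 0/1)."""
    return validate_epoch_series(pd.read_csv(path))


def classify_intensity(counts, cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS):
    """Assign awake epochs to SB / LPA / MVPA by counts/min.

    Total, monotone partition of [0, inf): SB up to sb_max, MVPA from
    mvpa_min, LPA in between. Works on scalars or arrays.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ActigraphyError("negative counts cannot be classified")
    out = np.where(x <= cutpoints.sb_max, SB, np.where(x >= cutpoints.mvpa_min, MVPA, LPA))
    return out.item() if np.isscalar(counts) or out.ndim == 0 else out


def _epoch_minutes(series: pd.DataFrame) -> float:
    if len(series) > 1:
        dt = (series["timestamp"].iloc[1] - series["timestamp"].iloc[0]).total_seconds()
        return dt / 60.0
    return 1.0


def detect_rest_intervals(
    series: pd.DataFrame,
    cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS,
    lux_threshold: float = 10.0,
    min_rest_minutes: float = 180.0,
    smooth_minutes: int = 15,
) -> list[RestInterval]:
    """Find one rest interval (bedtime → final wake) per night.

    Paired event markers are authoritative: consecutive marker presses
    whose gap is a plausible night (min_rest_minutes to 16 h) become the
    interval. Nights without usable markers fall back to the longest
    block per noon-to-noon window where lux is below ``lux_threshold``
    and the rolling-median counts are below the sleep/wake threshold.
    Raises if no night can be found.
    """
    series = validate_epoch_series(series)
    step = _epoch_minutes(series)
    intervals: list[RestInterval] = []

    marker_times = series.loc[series["marker"].astype(bool), "timestamp"].tolist()
    used = np.zeros(len(marker_times), dtype=bool)
    i = 0
    while i + 1 < len(marker_times):
        gap = (marker_times[i + 1] - marker_times[i]).total_seconds() / 60.0
        if min_rest_minutes <= gap <= 14 * 60:
            intervals.append(RestInterval(marker_times[i], marker_times[i + 1]))
            used[i] = used[i + 1] = True
            i += 2
        else:
            i += 1

    # heuristic for nights not covered by marker pairs
    quiet = (
        (series["lux"].to_numpy() < lux_threshold)
        & (
            series["counts"].rolling(max(1, int(smooth_minutes / step)), center=True, min_periods=1)
            .median()
            .to_numpy()
            < cutpoints.sleep_wake
        )
    )
    t0 = series["timestamp"].iloc[0].normalize() + pd.Timedelta(hours=12)
    if series["timestamp"].iloc[0] < t0:
        t0 -= pd.Timedelta(days=1)
    night_id = ((series["timestamp"] - t0) // pd.Timedelta(days=1)).to_numpy()
    covered_nights = {((iv.start - t0) // pd.Timedelta(days=1)) for iv in intervals}
    for nid in np.unique(night_id):
        if nid in covered_nights:
            continue
        mask = night_id == nid
        q = quiet & mask
        if not q.any():
            continue
        # longest run of quiet epochs in this noon-to-noon window
        idx = np.flatnonzero(q)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, breaks + 1)
        best = max(runs, key=len)
        if len(best) * step >= min_rest_minutes:
            start = series["timestamp"].iloc[best[0]]
            end = series["timestamp"].iloc[best[-1]] + pd.Timedelta(minutes=step)
            intervals.append(RestInterval(start, end))

    intervals.sort(key=lambda iv: iv.start)
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.end:
            raise ActigraphyError("overlapping rest intervals")
    if not intervals:
        raise ActigraphyError("no detectable night: participant flagged for exclusion")
    return intervals


def score_sleep(
    series: pd.DataFrame,
    interval: RestInterval,
    cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS,
) -> tuple[float, float]:
    """Minutes asleep and awake (WASO) within a rest interval.

    Sleep epochs are strictly below the sleep/wake threshold; an epoch at
    exactly the threshold is wake.
    """
    step = _epoch_minutes(series)
    in_iv = (series["timestamp"] >= interval.start) & (series["timestamp"] < interval.end)
    counts = series.loc[in_iv, "counts"].to_numpy()
    asleep = float((counts < cutpoints.sleep_wake).sum() * step)
    awake = float((counts >= cutpoints.sleep_wake).sum() * step)
    return asleep, awake


def segment_days(series: pd.DataFrame, rest_intervals: list[RestInterval]):
    """Day windows [bedtime_n, bedtime_{n+1}) from consecutive rest intervals.

    The partial recording before the first bedtime is dropped; a single
    night yields no complete day.
    """
    ivs = sorted(rest_intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ActigraphyError("overlapping rest intervals")
    return [(a.start, b.start, a) for a, b in zip(ivs, ivs[1:])]


def summarize_day(
    series: pd.DataFrame,
    window: tuple,
    cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS,
    index: int = 0,
    gap_tolerance_min: float = 2.0,
) -> DayRecord:
    """Score one bedtime-to-bedtime day into Sleep/SB/LPA/MVPA minutes.

    The opening night's sleep comes from ``score_sleep``; every awake
    epoch — WASO inside the rest interval included — goes through the
    intensity bands. Parts therefore sum exactly to the window length at
    epoch resolution. Epoch gaps longer than ``gap_tolerance_min``
    invalidate the day.
    """
    start, end, night = window
    step = _epoch_minutes(series)
    sel = series[(series["timestamp"] >= start) & (series["timestamp"] < end)]
    window_min = (end - start).total_seconds() / 60.0
    rec = DayRecord(index=index, date=start, sleep=0.0, sb=0.0, lpa=0.0, mvpa=0.0)
    if len(sel) * step < window_min - gap_tolerance_min:
        rec.valid = False
        rec.reason = "epoch gap exceeds tolerance"
        return rec

    ts = sel["timestamp"]
    counts = sel["counts"].to_numpy()
    in_night = ((ts >= night.start) & (ts < night.end)).to_numpy()
    sleeping = in_night & (counts < cutpoints.sleep_wake)
    awake = ~sleeping

    rec.sleep = float(sleeping.sum() * step)
    bands = classify_intensity(counts[awake], cutpoints)
    rec.sb = float((bands == SB).sum() * step)
    rec.lpa = float((bands == LPA).sum() * step)
    rec.mvpa = float((bands == MVPA).sum() * step)
    # carry the last classification across short gaps so parts match the window
    shortfall = window_min - rec.total_duration
    if 0 < shortfall <= gap_tolerance_min:
        rec.sb += shortfall
    return rec


@dataclass
class ParticipantSummary:
    """Averages across a participant's longest run of consecutive valid days."""

    included: bool
    reason: str
    n_days: int
    sleep: float = np.nan
    sb: float = np.nan
    lpa: float = np.nan
    mvpa: float = np.nan
    total_duration: float = np.nan


def _longest_consecutive_run(days: list[DayRecord]) -> list[DayRecord]:
    valid = [d for d in days if d.valid]
    if not valid:
        return []
    valid.sort(key=lambda d: d.date)
    runs, cur = [], [valid[0]]
    for prev, d in zip(valid, valid[1:]):
        if (d.date.normalize() - prev.date.normalize()) <= pd.Timedelta(days=1):
            cur.append(d)
        else:
            runs.append(cur)
            cur = [d]
    runs.append(cur)
    return max(runs, key=len)


def average_participant(days: list[DayRecord], min_days: int = 5) -> ParticipantSummary:
    """Mean minutes per behavior over the longest consecutive-day run.

    Participants with fewer than ``min_days`` consecutive valid days are
    excluded (the wear-validity rule), with the reason recorded.
    """
    run = _longest_consecutive_run(days)
    if len(run) < min_days:
        return ParticipantSummary(
            included=False,
            reason=f"only {len(run)} consecutive valid days (<{min_days})",
            n_days=len(run),
        )
    parts = np.stack([d.parts() for d in run])
    means = parts.mean(axis=0)
    return ParticipantSummary(
        included=True,
        reason="",
        n_days=len(run),
        sleep=float(means[0]),
        sb=float(means[1]),
        lpa=float(means[2]),
        mvpa=float(means[3]),
        total_duration=float(parts.sum(axis=1).mean()),
    )


def process_participant(
    series: pd.DataFrame,
    cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS,
    min_days: int = 5,
) -> tuple[ParticipantSummary, list[DayRecord]]:
    """Full scoring chain: rest intervals → day windows → day records → averages."""
    intervals = detect_rest_intervals(series, cutpoints)
    windows = segment_days(series, intervals)
    days = [
        summarize_day(series, w, cutpoints, index=i) for i, w in enumerate(windows)
    ]
    return average_participant(days, min_days=min_days), days
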