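"""Temporal alignment of all modalities to each depressed-mood rating.

Raw streams sample at very different rates (seconds-to-minutes for the
watch, hours for EMAs, days for cognitive sessions).  Each answered EMA
becomes one row of a 43-predictor feature table by aggregating or
carrying forward every stream relative to the rating timestamp:

1. time of day of the rating, binned at (06:00, 10:00, 14:00, 18:00);
2. anxiety, mean breathing time and breathing consistency taken
   concurrently from the same EMA;
3. cognitive and neural session scalars mapped from the nearest session
   by timestamp (ties broken toward the earlier session);
4. fats / sugars / caffeine summed over the prior 24 h of EMA reports;
5. heart rate averaged over a +-30 min window;
6. the four cumulative step features averaged over the prior 12 h;
7. the four exercise features averaged over the prior 24 h;
8. hours slept the previous night;
9. HRV (PPG inter-beat variability) std over a +-15 min window.

Lifestyle windows (diet, steps, exercise, sleep) look strictly backward
so that feature -> mood directionality is interpretable; heart rate and
HRV are the sole symmetric (+-) windows.  All windows are left-closed,
right-open; timestamps are timezone-naive local time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import schema
from .cognitive import read_cognitive_csv
from .datatypes import EMARecord, SleepEpisode, SyntheticSubject, WearableStream

logger = logging.getLogger(__name__)

MISSING = np.nan

#: (window, statistic) per wearable-derived feature, offsets in minutes.
_WEARABLE_RULES = {
    "heart_rate": ("heart_rate", (-30, 30), "mean"),
    "cumm_step_count": ("step_count", (-720, 0), "mean"),
    "cumm_step_distance": ("step_distance", (-720, 0), "mean"),
    "cumm_step_speed": ("step_speed", (-720, 0), "mean"),
    "cumm_step_calories": ("step_calories", (-720, 0), "mean"),
    "exercise_speed": ("exercise_speed", (-1440, 0), "mean"),
    "exercise_calories": ("exercise_calories", (-1440, 0), "mean"),
    "exercise_distance": ("exercise_distance", (-1440, 0), "mean"),
    "exercise_duration": ("exercise_duration", (-1440, 0), "mean"),
    "ppg_std": ("hrv_sample", (-15, 15), "std"),
}


def time_of_day_bin(timestamp) -> str:
    """Clock-time bin of a rating: [06,10) [10,14) [14,18) [18,24) -> bin1..bin4."""
    ts = pd.Timestamp(timestamp)
    minutes = ts.hour * 60 + ts.minute
    if minutes < 360:
        logger.warning("EMA timestamp %s before 06:00; assigned bin1", ts)
        return "bin1"
    if minutes < 600:
        return "bin1"
    if minutes < 840:
        return "bin2"
    if minutes < 1080:
        return "bin3"
    return "bin4"


def window_aggregate(stream: WearableStream, anchor, window, statistic: str) -> float:
    """Apply ``statistic`` to samples in [anchor+window[0], anchor+window[1]).

    ``window`` is a pair of signed offsets (``pd.Timedelta`` or minutes).
    Returns NaN when no samples fall in the window.  ``std`` uses the
    sample (n-1) definition and returns 0.0 for a single sample.
    """
    if statistic not in ("mean", "std", "sum"):
        raise ValueError(f"unknown statistic {statistic!r}")
    lo_off, hi_off = (
        pd.Timedelta(minutes=w) if not isinstance(w, pd.Timedelta) else w for w in window
    )
    if hi_off <= lo_off:
        raise ValueError("window must be non-degenerate (end > start)")
    anchor = np.datetime64(pd.Timestamp(anchor), "ns")
    lo = anchor + np.timedelta64(lo_off.to_timedelta64())
    hi = anchor + np.timedelta64(hi_off.to_timedelta64())
    i = np.searchsorted(stream.times, lo, side="left")
    j = np.searchsorted(stream.times, hi, side="left")
    vals = stream.values[i:j]
    if vals.size == 0:
        return MISSING
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "sum":
        return float(vals.sum())
    return float(vals.std(ddof=1)) if vals.size > 1 else 0.0


def previous_night_sleep(sleep_episodes, anchor) -> float:
    """Hours of the most recent sleep episode ending before the anchor.

    Only episodes whose end falls within 24 h of the anchor count; NaN if
    none.  If several candidate episodes overlap, the latest-ending wins
    (with a logged warning).
    """
    anchor = pd.Timestamp(anchor)
    candidates = [
        ep
        for ep in sleep_episodes
        if ep.end < anchor and (anchor - ep.end) <= pd.Timedelta(hours=24)
    ]
    if not candidates:
        return MISSING
    chosen = max(candidates, key=lambda ep: ep.end)
    overlapping = [
        ep for ep in candidates if ep is not chosen and ep.end > chosen.start
    ]
    if overlapping:
        logger.warning(
            "%d overlapping sleep episodes before %s; using the latest-ending",
            len(overlapping) + 1,
            anchor,
        )
    return chosen.hours


def _nearest_session(sessions, anchor):
    """Nearest cognitive session by |delta t|; ties go to the earlier session."""
    anchor = pd.Timestamp(anchor)
    return min(sessions, key=lambda s: (abs(anchor - s.timestamp), s.timestamp))


def _diet_sums(records: list[EMARecord], anchor) -> dict[str, float]:
    anchor = pd.Timestamp(anchor)
    lo = anchor - pd.Timedelta(hours=24)
    out = {"past_day_fats": 0.0, "past_day_sugars": 0.0, "past_day_caffeine": 0.0}
    for r in records:
        if lo < r.timestamp <= anchor:
            out["past_day_fats"] += r.fats
            out["past_day_sugars"] += r.sugars
            out["past_day_caffeine"] += r.caffeine
    return out


def build_feature_table(subject: SyntheticSubject) -> pd.DataFrame:
    """Align all streams to each answered EMA -> 43 predictors + target.

    Returns a chronologically ordered DataFrame indexed by EMA timestamp
    with the pinned 43 predictor columns followed by the ``depression``
    target.  Missing wearable-derived cells are NaN.
    """
    records = sorted(subject.ema_records, key=lambda r: r.timestamp)
    if not records:
        raise ValueError("cannot build a feature table without answered EMAs")
    rows = []
    for r in records:
        row: dict[str, object] = {"timestamp": r.timestamp}
        row["time_of_day"] = time_of_day_bin(r.timestamp)
        row["anxiety"] = r.anxiety
        row["mean_breathing_time"] = r.mean_breathing_time
        row["breathing_consistency"] = r.breathing_consistency
        row.update(_diet_sums(records, r.timestamp))
        for feat, (channel, window, stat) in _WEARABLE_RULES.items():
            stream = subject.wearable.get(channel)
            row[feat] = (
                window_aggregate(stream, r.timestamp, window, stat)
                if stream is not None and len(stream.times)
                else MISSING
            )
        row["prev_night_sleep"] = previous_night_sleep(
            subject.sleep_episodes, r.timestamp
        )
        session = _nearest_session(subject.cognitive_sessions, r.timestamp)
        for feat in schema.SESSION_FEATURES:
            row[feat] = session.metrics.get(feat, MISSING)
        row[schema.TARGET] = r.depression
        rows.append(row)
    table = pd.DataFrame(rows).set_index("timestamp")
    table = table[list(schema.FEATURES) + [schema.TARGET]]
    assert table.shape[1] == 44
    return table


# ---------------------------------------------------------------------------
# Disk round-trip: read the per-stream CSV layout written by pmhm.synthetic.


def read_subject(directory, subject_id: str | None = None) -> SyntheticSubject:
    """Load a subject from the one-CSV-per-stream directory layout."""
    from pathlib import Path

    from .datatypes import CognitiveSession

    d = Path(directory)
    ema = pd.read_csv(d / "ema.csv", parse_dates=["timestamp"])
    records = [
        EMARecord(
            timestamp=row.timestamp,
            depression=int(row.depression),
            anxiety=int(row.anxiety),
            mean_breathing_time=float(row.mean_breathing_time),
            breathing_consistency=float(row.breathing_consistency),
            fats=int(row.fats),
            sugars=int(row.sugars),
            caffeine=int(row.caffeine),
        )
        for row in ema.itertuples()
    ]

    wearable: dict[str, WearableStream] = {}

    def add_stream(channel: str, df: pd.DataFrame, value_col: str) -> None:
        wearable[channel] = WearableStream(
            channel=channel,
            times=df["timestamp"].to_numpy(dtype="datetime64[ns]"),
            values=df[value_col].to_numpy(dtype=float),
        )

    hr = pd.read_csv(d / "heart_rate.csv", parse_dates=["timestamp"])
    add_stream("heart_rate", hr, "value")
    hrv = pd.read_csv(d / "hrv.csv", parse_dates=["timestamp"])
    add_stream("hrv_sample", hrv, "value")
    steps = pd.read_csv(d / "steps.csv", parse_dates=["timestamp"])
    for ch in ("step_count", "step_distance", "step_speed", "step_calories"):
        add_stream(ch, steps, ch)
    exercise = pd.read_csv(d / "exercise.csv", parse_dates=["timestamp"])
    for ch in ("exercise_speed", "exercise_calories", "exercise_distance", "exercise_duration"):
        add_stream(ch, exercise, ch)

    sleep = pd.read_csv(d / "sleep.csv", parse_dates=["start", "end"])
    episodes = [SleepEpisode(row.start, row.end) for row in sleep.itertuples()]

    cog = read_cognitive_csv(d / "cognitive.csv")
    sessions = [
        CognitiveSession(
            day=int(row["day"]),
            timestamp=row["timestamp"],
            metrics={k: float(row[k]) for k in schema.SESSION_FEATURES},
        )
        for _, row in cog.iterrows()
    ]

    truth: dict = {}
    truth_path = d / "truth.json"
    if truth_path.exists():
        import json

        truth = json.loads(truth_path.read_text())

    return SyntheticSubject(
        subject_id=subject_id or d.name,
        ema_records=records,
        wearable=wearable,
        sleep_episodes=episodes,
        cognitive_sessions=sessions,
        truth=truth,
    )


def write_features(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True, index_label="timestamp")


def read_features(path) -> pd.DataFrame:
    table = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
    expected = list(schema.FEATURES) + [schema.TARGET]
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table[expected]
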