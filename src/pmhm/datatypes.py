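"""In-memory containers shared across pipeline stages.

These are plain dataclasses; tabular work happens in pandas once streams
are aligned into a feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Wearable channels carried as (timestamp, value) sample streams.
WEARABLE_CHANNELS = (
    "heart_rate",
    "step_count",
    "step_distance",
    "step_speed",
    "step_calories",
    "exercise_speed",
    "exercise_calories",
    "exercise_distance",
    "exercise_duration",
    "hrv_sample",
)


@dataclass
class EMARecord:
    """One answered momentary assessment: mood target plus concurrent predictors."""

    timestamp: pd.Timestamp
    depression: int
    anxiety: int
    mean_breathing_time: float
    breathing_consistency: float
    fats: int
    sugars: int
    caffeine: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.depression) <= 7:
            raise ValueError(f"depression must be in 1..7, got {self.depression}")
        if not 1 <= int(self.anxiety) <= 7:
            raise ValueError(f"anxiety must be in 1..7, got {self.anxiety}")
        for name in ("fats", "sugars", "caffeine"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")


@dataclass
class WearableStream:
    """Timestamped samples for one wearable channel."""

    channel: str
    times: np.ndarray  # datetime64[ns], strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in WEARABLE_CHANNELS:
            raise ValueError(f"unknown wearable channel {self.channel!r}")
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > np.timedelta64(0, "ns")).all():
            raise ValueError(f"timestamps must be strictly increasing in {self.channel}")


@dataclass(frozen=True)
class SleepEpisode:
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("sleep episode must end after it starts")

    @property
    def hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


@dataclass
class TrialSet:
    """Trial-level summary for one task in one session.

    Response-time statistics are carried as (mean, sd) summaries; the
    signal-detection counts feed hit/false-alarm rates.
    """

    rt_mean: float
    rt_sd: float
    n_hits: int = 0
    n_misses: int = 0
    n_false_alarms: int = 0
    n_correct_rejections: int = 0


@dataclass
class CognitiveSession:
    """One neurocognitive assessment session (study days 1, 15, 30).

    ``metrics`` holds the session-level scalars named in
    :data:`pmhm.schema.SESSION_FEATURES`; ``task_data`` optionally retains
    the per-task trial summaries they were derived from.
    """

    day: int
    timestamp: pd.Timestamp
    metrics: dict[str, float]
    task_data: dict[str, Any] = field(default_factory=dict)


@dataclass
class SyntheticSubject:
    """A full simulated subject with its generative ground truth."""

    subject_id: str
    ema_records: list[EMARecord]
    wearable: dict[str, WearableStream]
    sleep_episodes: list[SleepEpisode]
    cognitive_sessions: list[CognitiveSession]
    truth: dict[str, Any]
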