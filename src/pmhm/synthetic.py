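"""N-of-1 synthetic multimodal datasets with known planted structure.

The generator emulates a 30-day single-subject study: four EMA prompts per
day (08:00, 12:00, 16:00, 20:00) rating depressed mood and anxiety on 1-7
Likert scales alongside a 30-s breathing-tap assessment and past-4-h diet
counts; a smartwatch worn throughout (heart rate, step and exercise
aggregates, nightly sleep episodes, PPG-derived HRV); and neurocognitive
assessment sessions at the start, middle and end of the study.

The unobserved mood process is a stationary AR(1) on a latent continuous
scale,

    m_t = mu + phi * (m_{t-1} - mu) + sum_j beta_j * z_{j,t} + eps_t,

where the z_{j,t} are z-scored aligned feature values of planted-effect
predictors, and eps_t ~ Normal(0, noise_sd).  Observed ratings are the
latent value rounded then clipped to {1..7}.  Anxiety is the latent mood
plus independent noise, rediscretized, making it a strong concurrent
predictor by construction.  Planted effects give downstream stages a
recoverable ground truth.

All randomness flows from a single integer seed through one splittable
bit generator; two calls with the same spec are byte-identical on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .cognitive import session_metrics_from_tasks, sessions_to_table
from .datatypes import (
    CognitiveSession,
    EMARecord,
    SleepEpisode,
    SyntheticSubject,
    TrialSet,
    WearableStream,
)

__all__ = [
    "EffectSpec",
    "SubjectSpec",
    "simulate_latent_mood",
    "discretize_mood",
    "simulate_subject",
    "write_subject",
]

EFFECT_LAGS = ("concurrent", "past_24h", "past_12h", "previous_night")

_TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


@dataclass(frozen=True)
class EffectSpec:
    """A planted feature -> latent-mood effect.

    ``beta`` is in latent-mood units per standard deviation of the aligned
    feature value (drivers are z-scored before entering the AR(1) mean).
    ``lag`` documents the temporal relation the named feature already
    carries through the alignment rules; it is validated but the driver is
    always the aligned feature value itself.
    """

    feature_name: str
    beta: float
    lag: str = "concurrent"

    def __post_init__(self) -> None:
        if self.feature_name not in schema.FEATURES:
            raise ValueError(
                f"effect feature {self.feature_name!r} is not in the 43-feature schema"
            )
        if self.feature_name == "anxiety":
            raise ValueError(
                "cannot plant an effect on 'anxiety': it is generated from latent "
                "mood and would be circular"
            )
        if self.lag not in EFFECT_LAGS:
            raise ValueError(f"lag must be one of {EFFECT_LAGS}, got {self.lag!r}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass(frozen=True)
class SubjectSpec:
    """Generative world for one synthetic subject.

    Defaults state the study design: 30 days x 4 EMAs at 08/12/16/20,
    completion probability 0.775 (Binomial(120, 0.775) has mean 93,
    matching the reported 93 of 120 completed EMAs).
    """

    n_days: int = 30
    ema_times: tuple[str, ...] = ("08:00", "12:00", "16:00", "20:00")
    completion_prob: float = 0.775
    baseline_mood: float = 4.0
    ar_coefficient: float = 0.5
    noise_sd: float = 0.5
    anxiety_noise_sd: float = 0.7
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0
    start_date: str = "2023-03-06"
    subject_id: str = "S-01"

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError(f"n_days must be >= 2, got {self.n_days}")
        if not 0.0 < self.completion_prob <= 1.0:
            raise ValueError(
                f"completion_prob must be in (0, 1], got {self.completion_prob}"
            )
        if not abs(self.ar_coefficient) < 1.0:
            raise ValueError(
                f"ar_coefficient must satisfy |phi| < 1, got {self.ar_coefficient}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.anxiety_noise_sd < 0:
            raise ValueError(
                f"anxiety_noise_sd must be >= 0, got {self.anxiety_noise_sd}"
            )
        if not self.ema_times:
            raise ValueError("ema_times must be non-empty")
        object.__setattr__(self, "effects", tuple(self.effects))

    @property
    def n_scheduled(self) -> int:
        return self.n_days * len(self.ema_times)

    def schedule(self) -> pd.DatetimeIndex:
        """All scheduled EMA timestamps (answered or not)."""
        start = pd.Timestamp(self.start_date)
        stamps = [
            start + pd.Timedelta(days=d) + pd.Timedelta(f"{t}:00")
            for d in range(self.n_days)
            for t in self.ema_times
        ]
        return pd.DatetimeIndex(stamps)

    def session_days(self) -> tuple[int, int, int]:
        """Cognitive-session study days: start, midpoint, end (1-based)."""
        return 1, (self.n_days + 1) // 2, self.n_days


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_latent_mood(
    spec: SubjectSpec,
    effect_values: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent AR(1) mood trajectory, one value per scheduled EMA.

    ``effect_values`` is a (n_scheduled, n_effects) matrix of already
    scaled driver values matching ``spec.effects`` column-for-column; it
    defaults to zeros.  The process starts at its fixed point: with
    noise_sd = 0 and no effects the trajectory is constant at
    ``baseline_mood``.
    """
    T = spec.n_scheduled
    betas = np.array([e.beta for e in spec.effects], dtype=float)
    if effect_values is None:
        contrib = np.zeros(T)
    else:
        Z = np.asarray(effect_values, dtype=float)
        if Z.shape != (T, len(spec.effects)):
            raise ValueError(
                f"effect_values must have shape {(T, len(spec.effects))}, got {Z.shape}"
            )
        contrib = Z @ betas
    if rng is None:
        rng = _child_rngs(spec.seed, 7)[4]
    eps = rng.normal(0.0, spec.noise_sd, size=T) if spec.noise_sd > 0 else np.zeros(T)
    mu, phi = spec.baseline_mood, spec.ar_coefficient
    m = np.empty(T)
    prev = mu
    for t in range(T):
        m[t] = mu + phi * (prev - mu) + contrib[t] + eps[t]
        prev = m[t]
    return m


def discretize_mood(latent):
    """Map latent mood to the 1-7 Likert scale: round to nearest, then clip.

    Halves round up (monotone round-half-up, not banker's rounding).
    Accepts scalars or arrays; rejects non-finite input.
    """
    arr = np.asarray(latent, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("latent mood must be finite")
    out = np.clip(np.floor(arr + 0.5), 1, 7).astype(int)
    return int(out) if np.isscalar(latent) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Stream generators.  Cadences are stand-ins for the watch export: heart
# rate and HRV every 5 min, steps as hourly aggregates, at most one
# exercise bout per day, one sleep episode per night.


def _grid(start: pd.Timestamp, end: pd.Timestamp, minutes: int) -> np.ndarray:
    return pd.date_range(start, end, freq=f"{minutes}min", inclusive="left").to_numpy(
        dtype="datetime64[ns]"
    )


def _simulate_wearable(spec: SubjectSpec, rng: np.random.Generator):
    start = pd.Timestamp(spec.start_date) - pd.Timedelta(days=1)
    end = pd.Timestamp(spec.start_date) + pd.Timedelta(days=spec.n_days)
    streams: dict[str, WearableStream] = {}

    # Heart rate: 5-min cadence, mild circadian swing around 70 bpm.
    t_hr = _grid(start, end, 5)
    hours = (t_hr - t_hr.astype("datetime64[D]")).astype("timedelta64[m]").astype(float) / 60.0
    hr = 70.0 + 8.0 * np.sin(2 * np.pi * (hours - 15.0) / 24.0) + rng.normal(0, 5, len(t_hr))
    streams["heart_rate"] = WearableStream("heart_rate", t_hr, np.clip(hr, 40, 180))

    # HRV samples (inter-beat SDNN-like, ms): 5-min cadence.
    hrv = np.clip(45.0 + rng.normal(0, 8, len(t_hr)), 5.0, None)
    streams["hrv_sample"] = WearableStream("hrv_sample", t_hr.copy(), hrv)

    # Steps: hourly aggregates, active 07:00-22:00.
    t_st = _grid(start, end, 60)
    st_hours = (t_st - t_st.astype("datetime64[D]")).astype("timedelta64[h]").astype(int)
    active = (st_hours >= 7) & (st_hours < 22)
    count = np.where(active, rng.poisson(500, len(t_st)), 0).astype(float)
    distance = count * 0.00075 * (1 + rng.normal(0, 0.05, len(t_st)))  # km
    speed = np.where(count > 0, np.clip(rng.normal(4.8, 0.5, len(t_st)), 1.0, None), 0.0)
    calories = count * 0.04 * (1 + rng.normal(0, 0.05, len(t_st)))
    for ch, vals in (
        ("step_count", count),
        ("step_distance", np.clip(distance, 0, None)),
        ("step_speed", speed),
        ("step_calories", np.clip(calories, 0, None)),
    ):
        streams[ch] = WearableStream(ch, t_st.copy(), vals)

    # Exercise: at most one bout per day (p = 0.7), afternoon-weighted.
    ex_times, ex = [], {"exercise_speed": [], "exercise_calories": [],
                       "exercise_distance": [], "exercise_duration": []}
    n_cal_days = spec.n_days + 1
    for d in range(n_cal_days):
        if rng.random() >= 0.7:
            continue
        hour = rng.integers(7, 20)
        minute = rng.integers(0, 60)
        ts = start + pd.Timedelta(days=d, hours=int(hour), minutes=int(minute))
        duration = float(np.clip(rng.normal(40, 10), 10, 90))  # minutes
        speed_v = float(np.clip(rng.normal(8.0, 1.5), 3.0, None))  # km/h
        ex_times.append(np.datetime64(ts, "ns"))
        ex["exercise_duration"].append(duration)
        ex["exercise_speed"].append(speed_v)
        ex["exercise_distance"].append(speed_v * duration / 60.0)
        ex["exercise_calories"].append(duration * 7.0 * (1 + rng.normal(0, 0.1)))
    times = np.array(ex_times, dtype="datetime64[ns]")
    for ch, vals in ex.items():
        streams[ch] = WearableStream(ch, times.copy(), np.array(vals, dtype=float))

    # Sleep: one episode per night, ~23:00 onset, 4-10 h duration.
    episodes = []
    for d in range(n_cal_days):
        onset = (
            start + pd.Timedelta(days=d, hours=23)
            + pd.Timedelta(minutes=float(rng.normal(0, 30)))
        ).round("s")
        hours_slept = float(np.clip(rng.normal(7.5, 0.8), 4.0, 10.0))
        end = (onset + pd.Timedelta(hours=hours_slept)).round("s")
        episodes.append(SleepEpisode(onset, end))
    return streams, episodes


def _simulate_cognitive(spec: SubjectSpec, rng: np.random.Generator):
    """Three assessment sessions with plausible trial summaries and neural scalars."""
    # (signal trials, noise trials) per signal-detection task.
    n_trials = {"gw": (90, 90), "mf": (48, 48), "fo": (72, 72), "ls": (24, 24)}
    sessions = []
    start = pd.Timestamp(spec.start_date)
    for day in spec.session_days():
        task_data: dict[str, dict] = {}
        for task, (n_sig, n_noise) in n_trials.items():
            rt_mean = float(np.clip(rng.normal(0.45, 0.05), 0.2, None))
            rt_sd = float(np.clip(rng.normal(0.10, 0.02), 0.02, None))
            hit_rate = float(np.clip(rng.normal(0.85, 0.07), 0.5, 1.0))
            fa_rate = float(np.clip(rng.normal(0.15, 0.07), 0.0, 0.5))
            n_hits = int(round(hit_rate * n_sig))
            n_fa = int(round(fa_rate * n_noise))
            task_data[task] = {
                "trials": TrialSet(
                    rt_mean=rt_mean,
                    rt_sd=rt_sd,
                    n_hits=n_hits,
                    n_misses=n_sig - n_hits,
                    n_false_alarms=n_fa,
                    n_correct_rejections=n_noise - n_fa,
                )
            }
        task_data["ls"]["span"] = int(np.clip(round(rng.normal(5.5, 1.0)), 1, 8))
        task_data["tt"] = {
            "rt_mean": float(np.clip(rng.normal(4.0, 0.4), 1.0, None)),
            "rt_sd": float(np.clip(rng.normal(0.6, 0.1), 0.05, None)),
        }
        task_data["ld"] = {
            "base_n": 40,
            "base_rare_gain": int(rng.binomial(40, 0.45)),
            "exp_n": 40,
            "exp_rare_gain": int(rng.binomial(40, 0.62)),
        }
        task_data["neural"] = {
            name: float(rng.normal(0, 1)) for name in schema.NEURAL_FEATURES
        }
        metrics = session_metrics_from_tasks(task_data)
        sessions.append(
            CognitiveSession(
                day=day,
                timestamp=start + pd.Timedelta(days=day - 1, hours=10),
                metrics=metrics,
                task_data=task_data,
            )
        )
    return sessions


def _effect_drivers(spec: SubjectSpec, provisional: SyntheticSubject) -> np.ndarray:
    """Z-scored aligned feature values for each planted effect (T x J)."""
    from .features import build_feature_table

    table = build_feature_table(provisional)
    Z = np.empty((spec.n_scheduled, len(spec.effects)))
    for j, eff in enumerate(spec.effects):
        col = table[eff.feature_name]
        if col.dtype == object:  # categorical time_of_day -> ordinal codes
            col = col.map({b: i for i, b in enumerate(schema.TIME_OF_DAY_BINS)})
        v = col.to_numpy(dtype=float)
        mean = np.nanmean(v)
        sd = np.nanstd(v)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(
                f"planted-effect feature {eff.feature_name!r} has zero variance; "
                "its effect would be unidentifiable"
            )
        z = (v - mean) / sd
        Z[:, j] = np.nan_to_num(z, nan=0.0)
    return Z


def simulate_subject(spec: SubjectSpec) -> SyntheticSubject:
    """Generate a full synthetic subject; reproducible given ``spec.seed``."""
    rng_wear, rng_diet, rng_breath, rng_cog, rng_mood, rng_anx, rng_compl = _child_rngs(
        spec.seed, 7
    )
    T = spec.n_scheduled
    schedule = spec.schedule()

    streams, sleep_episodes = _simulate_wearable(spec, rng_wear)
    sessions = _simulate_cognitive(spec, rng_cog)

    fats = np.minimum(rng_diet.poisson(0.8, T), 6)
    sugars = np.minimum(rng_diet.poisson(0.8, T), 6)
    caffeine = np.minimum(rng_diet.poisson(0.5, T), 6)
    breath_mean = np.clip(rng_breath.normal(4.0, 0.4, T), 1.0, None)
    breath_cons = np.clip(rng_breath.normal(0.82, 0.06, T), 0.0, 1.0)

    if spec.effects:
        provisional = SyntheticSubject(
            subject_id=spec.subject_id,
            ema_records=[
                EMARecord(
                    timestamp=schedule[t],
                    depression=4,
                    anxiety=4,
                    mean_breathing_time=float(breath_mean[t]),
                    breathing_consistency=float(breath_cons[t]),
                    fats=int(fats[t]),
                    sugars=int(sugars[t]),
                    caffeine=int(caffeine[t]),
                )
                for t in range(T)
            ],
            wearable=streams,
            sleep_episodes=sleep_episodes,
            cognitive_sessions=sessions,
            truth={},
        )
        Z = _effect_drivers(spec, provisional)
    else:
        Z = None

    latent = simulate_latent_mood(spec, effect_values=Z, rng=rng_mood)
    depression = discretize_mood(latent)
    anxiety = discretize_mood(latent + rng_anx.normal(0, spec.anxiety_noise_sd, T))
    answered = rng_compl.random(T) < spec.completion_prob

    records = [
        EMARecord(
            timestamp=schedule[t],
            depression=int(depression[t]),
            anxiety=int(anxiety[t]),
            mean_breathing_time=float(breath_mean[t]),
            breathing_consistency=float(breath_cons[t]),
            fats=int(fats[t]),
            sugars=int(sugars[t]),
            caffeine=int(caffeine[t]),
        )
        for t in range(T)
        if answered[t]
    ]

    truth = {
        "seed": spec.seed,
        "subject_id": spec.subject_id,
        "latent_mood": [float(x) for x in latent],
        "depression": [int(x) for x in depression],
        "answered": [bool(a) for a in answered],
        "effects": [
            {"feature_name": e.feature_name, "beta": e.beta, "lag": e.lag}
            for e in spec.effects
        ],
    }
    return SyntheticSubject(
        subject_id=spec.subject_id,
        ema_records=records,
        wearable=streams,
        sleep_episodes=sleep_episodes,
        cognitive_sessions=sessions,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Disk layout: one CSV per stream, ISO-8601 timestamps, plus truth.json.


def _stream_frame(subject: SyntheticSubject, channels: list[str], names: list[str]):
    first = subject.wearable[channels[0]]
    data = {"timestamp": first.times}
    for ch, name in zip(channels, names):
        data[name] = subject.wearable[ch].values
    return pd.DataFrame(data)


def write_subject(subject: SyntheticSubject, directory) -> Path:
    """Write a subject as per-stream CSVs plus truth.json; returns the dir."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    kw = {"index": False, "date_format": _TIMESTAMP_FORMAT}

    ema = pd.DataFrame(
        {
            "timestamp": [r.timestamp for r in subject.ema_records],
            "depression": [r.depression for r in subject.ema_records],
            "anxiety": [r.anxiety for r in subject.ema_records],
            "mean_breathing_time": [r.mean_breathing_time for r in subject.ema_records],
            "breathing_consistency": [
                r.breathing_consistency for r in subject.ema_records
            ],
            "fats": [r.fats for r in subject.ema_records],
            "sugars": [r.sugars for r in subject.ema_records],
            "caffeine": [r.caffeine for r in subject.ema_records],
        }
    )
    ema.to_csv(d / "ema.csv", **kw)

    hr = subject.wearable["heart_rate"]
    pd.DataFrame({"timestamp": hr.times, "value": hr.values}).to_csv(
        d / "heart_rate.csv", **kw
    )
    hrv = subject.wearable["hrv_sample"]
    pd.DataFrame({"timestamp": hrv.times, "value": hrv.values}).to_csv(
        d / "hrv.csv", **kw
    )
    _stream_frame(
        subject,
        ["step_count", "step_distance", "step_speed", "step_calories"],
        ["step_count", "step_distance", "step_speed", "step_calories"],
    ).to_csv(d / "steps.csv", **kw)
    _stream_frame(
        subject,
        ["exercise_speed", "exercise_calories", "exercise_distance", "exercise_duration"],
        ["exercise_speed", "exercise_calories", "exercise_distance", "exercise_duration"],
    ).to_csv(d / "exercise.csv", **kw)
    pd.DataFrame(
        {
            "start": [e.start for e in subject.sleep_episodes],
            "end": [e.end for e in subject.sleep_episodes],
        }
    ).to_csv(d / "sleep.csv", **kw)

    sessions_to_table(subject.cognitive_sessions).to_csv(d / "cognitive.csv", **kw)

    (d / "truth.json").write_text(json.dumps(subject.truth, indent=1, sort_keys=True))
    return d


def spec_with_seed(spec: SubjectSpec, seed: int, subject_id: str | None = None) -> SubjectSpec:
    """Copy a spec with a new seed (and optionally id) for replicate subjects."""
    kwargs = {"seed": int(seed)}
    if subject_id is not None:
        kwargs["subject_id"] = subject_id
    return replace(spec, **kwargs)
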