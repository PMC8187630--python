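"""Behavioral metrics from neurocognitive task logs.

Implements the session-level scalar metrics used as model predictors:

* ``consistency`` = 1 - CV, where CV is the coefficient of variation of
  response times (higher = steadier responding);
* ``scaled_dprime`` = signal-detection sensitivity d' = z(hits) - z(false
  alarms), scaled by its theoretical maximum under rate clamping so it
  lives in [0, 1];
* ``efficiency`` = scaled-d' x speed, with speed = ln(1 / mean RT);
* reward-task expected-value design quantities and choice-bias metrics.

Rates are clamped to [0.01, 0.99] before the probit transform; the
resulting ceiling z(0.99) - z(0.01) = 4.6527 is the scaling constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import CognitiveSession, TrialSet
from .schema import SESSION_FEATURES

__all__ = [
    "MetricError",
    "DPRIME_MAX",
    "consistency",
    "consistency_from_stats",
    "scaled_dprime",
    "efficiency",
    "DoorSpec",
    "RewardBlockSpec",
    "BASELINE_BLOCK",
    "EXPERIMENTAL_BLOCK",
    "door_ev",
    "reward_choice_metrics",
    "session_metrics_from_tasks",
    "sessions_to_table",
    "read_cognitive_csv",
    "write_session_metrics",
]


class MetricError(ValueError):
    """A metric is undefined for the given inputs."""


#: Rate clamp applied before the probit transform.
RATE_CLAMP = (0.01, 0.99)

#: Theoretical maximum d' under the clamp: z(0.99) - z(0.01) ~= 4.6527.
DPRIME_MAX = float(norm.ppf(RATE_CLAMP[1]) - norm.ppf(RATE_CLAMP[0]))


def consistency_from_stats(rt_mean: float, rt_sd: float) -> float:
    """1 - CV from precomputed response-time mean and sd."""
    if not rt_mean > 0:
        raise MetricError("consistency undefined: mean response time must be > 0")
    return 1.0 - rt_sd / rt_mean


def consistency(response_times) -> float:
    """1 - CV of a sequence of response times (sample sd, n-1 denominator)."""
    rts = np.asarray(response_times, dtype=float)
    if rts.size < 2:
        raise MetricError("consistency undefined: need at least 2 response times")
    mean = float(rts.mean())
    if mean <= 0:
        raise MetricError("consistency undefined: mean response time must be > 0")
    return consistency_from_stats(mean, float(rts.std(ddof=1)))


def scaled_dprime(hit_rate: float, fa_rate: float) -> float:
    """d' = z(hits) - z(false alarms), scaled to [0, 1] by its clamped ceiling."""
    if not (np.isfinite(hit_rate) and np.isfinite(fa_rate)):
        raise MetricError("scaled_dprime: rates must be finite")
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise MetricError("scaled_dprime: rates must lie in [0, 1]")
    lo, hi = RATE_CLAMP
    h = min(max(hit_rate, lo), hi)
    f = min(max(fa_rate, lo), hi)
    d = float(norm.ppf(h) - norm.ppf(f))
    return float(np.clip(d / DPRIME_MAX, 0.0, 1.0))


def efficiency(scaled_d: float, mean_rt: float) -> float:
    """scaled-d' x speed, with speed = ln(1 / mean RT in seconds)."""
    if not mean_rt > 0:
        raise MetricError("efficiency undefined: mean response time must be > 0")
    return scaled_d * math.log(1.0 / mean_rt)


# ---------------------------------------------------------------------------
# Reward task ("Lucky Door") design quantities and choice metrics.


@dataclass(frozen=True)
class DoorSpec:
    gain_amount: float
    p_gain: float
    loss_amount: float
    p_loss: float

    def __post_init__(self) -> None:
        for p in (self.p_gain, self.p_loss):
            if not 0.0 <= p <= 1.0:
                raise ValueError("door probabilities must lie in [0, 1]")
        if abs(self.p_gain + self.p_loss - 1.0) > 1e-12:
            raise ValueError("door probabilities must sum to 1")

    @property
    def ev(self) -> float:
        return self.gain_amount * self.p_gain + self.loss_amount * self.p_loss


@dataclass(frozen=True)
class RewardBlockSpec:
    rare_gain_door: DoorSpec
    rare_loss_door: DoorSpec

    def door(self, name: str) -> DoorSpec:
        if name == "rare_gain":
            return self.rare_gain_door
        if name == "rare_loss":
            return self.rare_loss_door
        raise ValueError(f"unknown door {name!r}")


#: Baseline block: +-70 at p=0.3 / -+30 at p=0.7 -- equal EV for both doors.
BASELINE_BLOCK = RewardBlockSpec(
    rare_gain_door=DoorSpec(70.0, 0.3, -30.0, 0.7),
    rare_loss_door=DoorSpec(-70.0, 0.3, 30.0, 0.7),
)

#: Experimental block: rare-gain door 60 at p=0.3 / -20 at p=0.7, rare-loss
#: door -60 at p=0.3 / 20 at p=0.7 -- a cumulative EV gap of 80 coins per
#: 10 trials favoring the rare-gain door.
EXPERIMENTAL_BLOCK = RewardBlockSpec(
    rare_gain_door=DoorSpec(60.0, 0.3, -20.0, 0.7),
    rare_loss_door=DoorSpec(-60.0, 0.3, 20.0, 0.7),
)


def door_ev(block: RewardBlockSpec, door: str, n_trials: int) -> float:
    """Cumulative expected coin payoff of one door over ``n_trials`` choices."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return block.door(door).ev * n_trials


def reward_choice_metrics(choices_baseline, choices_experimental) -> tuple[float, float]:
    """(gain-vs-loss bias, rare-gain choice difference) from door-choice sequences.

    ``gl_bias`` is the fraction of rare-loss-door (frequent-gain) choices
    minus rare-gain-door choices on the baseline block, so positive values
    mean a preference for frequent immediate gains.  ``rare_gain_diff`` is
    the rare-gain choice fraction in the experimental block minus baseline,
    indexing sensitivity to the planted EV advantage.
    """

    def frac_rare_gain(choices) -> float:
        seq = list(choices)
        if not seq:
            raise MetricError("reward_choice_metrics: empty choice sequence")
        bad = set(seq) - {"rare_gain", "rare_loss"}
        if bad:
            raise ValueError(f"unknown door labels: {sorted(bad)}")
        return sum(c == "rare_gain" for c in seq) / len(seq)

    g_base = frac_rare_gain(choices_baseline)
    g_exp = frac_rare_gain(choices_experimental)
    gl_bias = (1.0 - g_base) - g_base
    return gl_bias, g_exp - g_base


# ---------------------------------------------------------------------------
# Session assembly: trial summaries -> the 25 session-level schema scalars.

#: Tasks with consistency + efficiency metrics (signal-detection designs).
SD_TASKS = ("gw", "mf", "fo", "ls")


def session_metrics_from_tasks(task_data: dict) -> dict[str, float]:
    """Compute the behavioral session scalars from per-task trial summaries.

    ``task_data`` maps task codes to dicts: ``gw``/``mf``/``fo``/``ls``
    carry a :class:`TrialSet` under ``"trials"`` (``ls`` also ``"span"``);
    ``tt`` carries breathing-tap ``rt_mean``/``rt_sd``; ``ld`` carries
    baseline/experimental rare-gain choice counts.  Neural scalars present
    under ``"neural"`` are passed through unchanged.
    """
    metrics: dict[str, float] = {}
    for task in SD_TASKS:
        t: TrialSet = task_data[task]["trials"]
        metrics[f"{task}_consistency"] = consistency_from_stats(t.rt_mean, t.rt_sd)
        hr = t.n_hits / max(t.n_hits + t.n_misses, 1)
        fr = t.n_false_alarms / max(t.n_false_alarms + t.n_correct_rejections, 1)
        sd = scaled_dprime(hr, fr)
        metrics[f"{task}_efficiency"] = efficiency(sd, t.rt_mean)
    span = int(task_data["ls"]["span"])
    if not 1 <= span <= 8:
        raise MetricError(f"working-memory span must be in 1..8, got {span}")
    metrics["ls_span"] = float(span)

    tt = task_data["tt"]
    metrics["tt_consistency"] = consistency_from_stats(tt["rt_mean"], tt["rt_sd"])
    metrics["tt_mean_breathing_time"] = float(tt["rt_mean"])

    ld = task_data["ld"]
    base = ["rare_gain"] * ld["base_rare_gain"] + ["rare_loss"] * (
        ld["base_n"] - ld["base_rare_gain"]
    )
    exp = ["rare_gain"] * ld["exp_rare_gain"] + ["rare_loss"] * (
        ld["exp_n"] - ld["exp_rare_gain"]
    )
    gl_bias, rare_gain_diff = reward_choice_metrics(base, exp)
    metrics["LD_GL_bias"] = gl_bias
    metrics["LD_RareG_diff"] = rare_gain_diff

    metrics.update(task_data.get("neural", {}))
    return metrics


def sessions_to_table(sessions: list[CognitiveSession]) -> pd.DataFrame:
    """Wide per-session table: one row per session, the 25 schema scalars."""
    rows = []
    for s in sessions:
        row = {"day": s.day, "timestamp": s.timestamp}
        row.update({k: s.metrics.get(k, np.nan) for k in SESSION_FEATURES})
        rows.append(row)
    return pd.DataFrame(rows)


def read_cognitive_csv(path) -> pd.DataFrame:
    """Read a per-session cognitive/neural scalar table (cognitive.csv dialect)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in SESSION_FEATURES if c not in df.columns]
    if missing:
        raise ValueError(f"cognitive table missing columns: {missing}")
    return df


def write_session_metrics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
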