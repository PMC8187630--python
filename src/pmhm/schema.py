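"""Pinned per-subject feature schema.

Every stage of the pipeline speaks this schema: 43 predictor columns per
subject, one row per answered EMA, with the depressed-mood Likert rating
(1-7) as target.  The roster groups into four blocks:

* EMA block (7) -- concurrent self-report and 30-s breathing-tap metrics,
  plus past-day diet counts.
* Wearable block (11) -- smartwatch heart rate, step and exercise
  aggregates, previous-night sleep, and PPG-derived HRV.
* Behavioral block (13) -- per-session cognitive task metrics (consistency,
  scaled-d' efficiency, working-memory span, breathing, reward biases).
* Neural block (12) -- EEG source-localized band-amplitude scalars for the
  left DLPFC and dACC regions, entering as precomputed per-session values.

Task prefixes: gw = inhibitory control ("Go Wait"), mf = interference
("Middle Fish"), ls = working memory ("Lost Star"), fo = emotion bias
("Face Off"), tt = internal attention ("Two Tap"), LD = reward ("Lucky
Door").
"""

from __future__ import annotations

TARGET = "depression"

TIME_OF_DAY_BINS = ("bin1", "bin2", "bin3", "bin4")

EMA_FEATURES = (
    "time_of_day",
    "anxiety",
    "mean_breathing_time",
    "breathing_consistency",
    "past_day_fats",
    "past_day_sugars",
    "past_day_caffeine",
)

WEARABLE_FEATURES = (
    "heart_rate",
    "cumm_step_count",
    "cumm_step_distance",
    "cumm_step_speed",
    "cumm_step_calories",
    "exercise_speed",
    "exercise_calories",
    "exercise_distance",
    "exercise_duration",
    "prev_night_sleep",
    "ppg_std",
)

BEHAVIORAL_FEATURES = (
    "gw_consistency",
    "gw_efficiency",
    "mf_consistency",
    "mf_efficiency",
    "fo_consistency",
    "fo_efficiency",
    "ls_consistency",
    "ls_efficiency",
    "ls_span",
    "tt_consistency",
    "tt_mean_breathing_time",
    "LD_GL_bias",
    "LD_RareG_diff",
)

NEURAL_FEATURES = (
    "gw_theta_leftDLPFC",
    "gw_theta_dACC",
    "mf_theta_leftDLPFC",
    "mf_theta_dACC",
    "ls_theta_leftDLPFC",
    "ls_theta_dACC",
    "fo_theta_leftDLPFC",
    "fo_theta_dACC",
    "tt_alpha_leftDLPFC",
    "GLbias_leftDLPFC",
    "GLbias_dACC",
    "diff_rareLG_leftDLPFC",
)

FEATURES = EMA_FEATURES + WEARABLE_FEATURES + BEHAVIORAL_FEATURES + NEURAL_FEATURES
assert len(FEATURES) == 43, "pinned schema must have exactly 43 predictors"
assert len(set(FEATURES)) == 43

#: Session-level neurocognitive scalars carried onto each EMA row.
SESSION_FEATURES = BEHAVIORAL_FEATURES + NEURAL_FEATURES

# ---------------------------------------------------------------------------
# Preprocessing column groups (they partition the 43 predictors).

DISCRETE_COLUMNS = ("time_of_day",)
WATCH_EMA_COLUMNS = tuple(c for c in EMA_FEATURES if c != "time_of_day") + WEARABLE_FEATURES
NEUROCOG_COLUMNS = SESSION_FEATURES

assert set(DISCRETE_COLUMNS) | set(WATCH_EMA_COLUMNS) | set(NEUROCOG_COLUMNS) == set(FEATURES)

# ---------------------------------------------------------------------------
# Feature -> interpretive domain, for top-k Shapley frequency summaries.

DOMAINS = ("anxiety", "physical_activity", "diet", "breathing_stress",
           "sleep", "neurocognitive", "other")

FEATURE_DOMAIN: dict[str, str] = {}
FEATURE_DOMAIN["anxiety"] = "anxiety"
for _f in ("cumm_step_count", "cumm_step_distance", "cumm_step_speed",
           "cumm_step_calories", "exercise_speed", "exercise_calories",
           "exercise_distance", "exercise_duration"):
    FEATURE_DOMAIN[_f] = "physical_activity"
for _f in ("past_day_fats", "past_day_sugars", "past_day_caffeine"):
    FEATURE_DOMAIN[_f] = "diet"
for _f in ("mean_breathing_time", "breathing_consistency", "heart_rate", "ppg_std"):
    FEATURE_DOMAIN[_f] = "breathing_stress"
FEATURE_DOMAIN["prev_night_sleep"] = "sleep"
for _f in SESSION_FEATURES:
    FEATURE_DOMAIN[_f] = "neurocognitive"
FEATURE_DOMAIN["time_of_day"] = "other"

assert set(FEATURE_DOMAIN) == set(FEATURES)
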