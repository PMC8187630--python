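# Methods

This note documents the models and procedures `pmhm` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducing results. It states no empirical numbers beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## 1. The modeling problem

One subject contributes up to 120 momentary depressed-mood ratings
(1–7 Likert, 4×/day × 30 days) together with concurrent anxiety ratings,
a 30-s breathing-tap assay, past-4-h diet counts, continuous smartwatch
streams, and three neurocognitive assessment sessions. The goal is a
per-person regression ŷ = f(x) of the momentary rating on 43 aligned
predictors, followed by a per-person attribution of predictions to
features. No data are pooled across subjects.

## 2. Feature alignment (43 predictors)

All streams are resampled to the rating timestamps ("anchors"):

| block | features | rule |
|---|---|---|
| EMA (7) | time_of_day; anxiety; mean_breathing_time; breathing_consistency; past_day fats/sugars/caffeine | bins [06,10)/[10,14)/[14,18)/[18,24); concurrent; diet summed over (t−24 h, t] |
| wearable (11) | heart_rate; 4 cumulative step features; 4 exercise features; prev_night_sleep; ppg_std | mean over ±30 min; mean over [t−12 h, t); mean over [t−24 h, t); latest episode ending < t within 24 h; std over ±15 min |
| behavioral (13) | consistency+efficiency for 4 signal-detection tasks; WM span; breathing consistency+time; 2 reward-choice biases | nearest session by \|Δt\|, ties to the earlier session |
| neural (12) | task theta for left DLPFC + dACC (8); internal-attention alpha left DLPFC; reward GL-bias both regions; reward EV-contrast left DLPFC | same nearest-session rule |

Conventions: all windows left-closed right-open; timestamps
timezone-naive local; an anchor before 06:00 falls in bin1 with a logged
warning; empty windows yield an explicit missing cell; a single HRV
sample yields std 0. Session scalars are carried between sessions as a
step function (carry-nearest), not linearly extrapolated — with three
sessions, linear extrapolation would let a single noisy session dominate.
Lifestyle windows (diet, steps, exercise, sleep) look strictly backward;
heart rate and HRV are the only symmetric windows, so a property test
asserts that perturbing post-anchor samples never changes backward-looking
cells.

## 3. Cognitive metrics

* consistency = 1 − CV, CV = sd(RT)/mean(RT), sample (n−1) sd.
* d′ = z(hit rate) − z(false-alarm rate), with rates clamped to
  [0.01, 0.99] before the probit; scaled d′ = d′ / (z(0.99) − z(0.01))
  ≈ d′/4.6527, clipped to [0, 1]. The clamp bounds were chosen because
  their probit ceiling reproduces the conventional printed scaling
  constant 4.65 at two decimals.
* efficiency = scaled d′ × ln(1/mean RT). Natural log; since features are
  max-abs scaled downstream, the log base only rescales the feature.
* Reward task: door EV = gain·p(gain) + loss·p(loss), cumulative EV =
  per-trial EV × trials. With the experimental payoffs (rare-gain door:
  +60 @ 0.3 / −20 @ 0.7; rare-loss door: −60 @ 0.3 / +20 @ 0.7) the
  cumulative 10-trial EVs are +40/−40 coins (gap 80); the baseline
  payoffs (±70 @ 0.3 / ∓30 @ 0.7) give zero for both doors.
  gl_bias = fraction of rare-loss-door choices minus rare-gain-door
  choices on the baseline block (positive = preference for frequent
  immediate gains); rare_gain_diff = rare-gain fraction, experimental
  minus baseline.

## 4. Preprocessing

Three disjoint column groups are processed independently and the fitted
object is strictly train-only (its JSON serialization is asserted
invariant to anything done at transform time):

* **discrete** (time_of_day): most-frequent-class imputation, ordinal
  codes 0..3; unseen/missing categories map to the training mode with a
  logged warning.
* **continuous watch+EMA** (17 columns): round-robin multivariate
  imputation. Missing cells are initialized with column means; for 10
  rounds, columns are visited in ascending-missingness order (stable by
  index) and each is regressed on all others over its originally-observed
  rows; only originally-missing cells are overwritten. The per-column
  estimator is a closed-form ridge with unpenalized intercept and
  α = 1e−6 (near-OLS; the penalty only guards exact collinearity). The
  variant is deterministic (conditional mean, no posterior sampling) so
  runs are exactly reproducible; a test cross-checks it against
  scikit-learn's chained-equations imputer configured equivalently.
  Transform replays the stored per-round regressors on new rows without
  refitting.
* **continuous neurocognitive** (25 columns): constant fill 0 — these
  have at most three distinct values per subject, too coarse for
  regression imputation, and 0 is neutral under max-abs scaling.

All continuous columns are then divided by the training per-column
maximum absolute value (an all-zero column gets scale 1). No centering,
so exact zeros survive and test values may exceed |1|.

## 5. Nested cross-validation and strategies

Outer: simple 4-fold, shuffled with the run seed. Inner (within each
outer training set): repeated 4-fold × 10 repeats. Grid search minimizes
mean inner MAPE; ties go to the earlier grid entry. Preprocessing is
fitted inside every inner training split and once per outer training
fold, never on held-out rows. At least 16 rows are required; subjects
below that are skipped with a warning (the known too-little-data failure
mode). A second guard flags subjects whose ratings are ≥ 90% one value
(the known low-variability failure mode) but still fits.

Strategies and default grids (compact, centered on library defaults,
≤ 12 points; fixed here for reproducibility because no canonical grids
exist): en α∈{0.01,0.1,1}×l1∈{0.2,0.5,0.8}; rf depth∈{None,4}×leaf∈{1,3}
(60 trees); gb trees∈{50,100}×depth∈{2,3}; ab trees∈{25,50}×lr∈{0.5,1};
pr α∈{0.01,0.1,1}; sv C∈{0.5,2,8}×ε∈{0.05,0.2}. The Poisson regressor
treats ratings 1–7 as valid positive counts with the canonical log link.
The voting regressor is the unweighted mean of the six tuned base
estimators of the same outer fold and is evaluated as a seventh
candidate; consequently the selected best strategy's mean MAPE can never
exceed vr's. `reduced_grids()` shrinks every grid to one point for fast
end-to-end runs; selection over a singleton grid is the identity, so the
nested evaluator skips the inner scoring loop in that case (the scheme is
unchanged, only a no-op search is elided).

Outer folds are shuffled rather than chronological. With a stationary
AR(1)-like target and concurrent predictors this mirrors the random-split
convention; for strongly trending real data a time-blocked split would be
more conservative — a known limitation, kept configurable via the seed
rather than silently changed.

Reported per strategy: mean and sd (n−1, across the 4 outer folds) of
MAPE and MAE. Best model: argmin mean MAPE, ties by mean MAE, then the
fixed order en, rf, gb, ab, pr, sv, vr.

Cohort statistics: paired t-test of best-vs-vr MAPE across subjects;
per-subject Spearman ρ between concatenated out-of-fold predictions and
actuals with Fisher-z 95% CIs; under-/over-estimation percentages with a
signed-rank test. Predictions are rounded to the Likert grid before the
under/over comparison, so "exact" predictions are possible and the two
percentages need not sum to 100.

## 6. Permutation Shapley explainer

The value of a feature coalition S for instance x is the mean model
prediction over background rows with the features in S set to x. For
each sampled permutation the explainer walks the ordering forward and
then reversed, toggling features from background to instance values and
crediting each prediction delta to the toggled feature; all 2(p+1)
coalition matrices of a permutation are stacked into a single model call.
Every walk telescopes to f(x) − base exactly, so additivity holds to
floating-point for the averaged values — asserted at 1e−6 for every
explanation. One forward-reverse pass is exact through second-order
interactions; for additive models φⱼ = βⱼ(xⱼ − mean background xⱼ)
exactly, a frozen test oracle. An exact 2^p enumeration oracle (refusing
p > 12) provides the independent cross-check (±0.01 at 500 permutations
on 6-feature tree models).

Defaults: 200 permutations (unstated in common practice; enough for
stable rankings at p = 43), background = the subject's own training rows
of the explaining fold, subsampled to ≤ 100 with a fixed seed
(idiographic: no other subject's data is ever used). Explanations are
computed on out-of-fold instances with that fold's fitted model, so
attributions describe predictions actually reported. Rankings use mean
|φ| per feature; domain frequencies count the fraction of subjects with
at least one top-5 feature per domain (anxiety, physical activity, diet,
breathing/stress, sleep, neurocognitive, other). Heart rate and HRV are
grouped with breathing under stress physiology; time-of-day falls in
"other".

## 7. Synthetic world

The generator's defaults state the study design: 30 days × 4 EMAs at
08:00/12:00/16:00/20:00; independent per-EMA completion with
p = 0.775, chosen so the answered-EMA count is Binomial(120, 0.775) with
mean 93, matching the reported average completion; sessions at days 1,
15, 30.

Latent mood is a stationary AR(1), m_t = μ + φ(m_{t−1} − μ) + Σⱼ βⱼ
z_{j,t} + ε_t, started at its fixed point, with μ = 4 (scale midpoint),
φ = 0.5 (moderate momentary persistence), ε ~ N(0, 0.5). Ratings are
round-half-up then clipped to {1..7} (the simplest monotone latent-to-
Likert map). Anxiety is the latent mood plus N(0, 0.7), rediscretized —
a strong concurrent correlate by construction, giving the
anxiety-as-top-predictor phenomenon a synthetic analogue with a
configurable coupling. Planted effects name any schema feature except
anxiety (which is endogenous); their drivers are the *actual aligned
feature values*, z-scored, so β is in latent-mood units per driver SD
and downstream recovery tests have exact ground truth.

Wearable cadences are stand-ins (the export granularity of consumer
watches varies): heart rate and HRV every 5 min (circadian mean 70 bpm ±
noise; SDNN-like 45 ± 8 ms), steps as hourly aggregates active
07:00–22:00, at most one exercise bout per day (p = 0.7), one sleep
episode per night (~23:00 onset, 4–10 h). Diet counts are capped Poisson
draws per EMA; breathing-tap summaries are Gaussian around 4 s. Cognitive
sessions draw trial-summary statistics (RT mean/sd, hit and false-alarm
counts, WM span, door choices) and N(0,1) neural scalars; behavioral
metrics are then *computed from them* through the metrics module, so the
formula path is exercised end to end. All randomness flows from one
`SeedSequence`; identical specs produce byte-identical CSVs.

What the generator does **not** emulate — hence what a green test does
not establish: circadian/weekday structure in mood, autocorrelated or
missing-not-at-random EMA skipping, watch-charging gaps, drift or
practice effects in cognitive sessions, heavy-tailed sensor noise, or
any causal feedback from mood to lifestyle. Recovery results certify the
pipeline's mechanics (alignment, leakage-safety, selection, attribution),
not its performance on real populations.

### Recovery world (frozen)

The end-to-end recovery check plants one effect, β = 1.5 on
past_day_caffeine, noise_sd = 0.5, complete data, 20 replicate seeds
(100–119), reduced grids; the planted feature must reach the top-5
Shapley ranking in ≥ 80% of replicates. These values were fixed before
measuring and not revisited.

## 8. Known limitations

* The exact roster behind the pinned 43-feature schema is a
  reconstruction from the described methods and figure labels; real
  deployments may carry different neural contrasts.
* The imputer is the deterministic conditional-mean variant of chained
  equations; no multiple-imputation uncertainty is propagated.
* Outer folds ignore temporal ordering (see §5).
* MAPE on a 1–7 scale is coarse: a 1-point miss at rating 1 is a 100%
  error, so MAPE and MAE should be read together.
* The voting ensemble uses a plain unweighted mean; no stacking or
  weight learning.
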