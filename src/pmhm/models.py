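"""Nested cross-validated model selection over seven regression strategies.

Each subject's depressed-mood ratings are modeled with six base
strategies -- elastic net (en), random forest (rf), gradient boosted
trees (gb), Ada boosted trees (ab), Poisson regressor (pr), support
vector regressor (sv) -- plus a voting regressor (vr) composed of the six
tuned base estimators.  Hyperparameters are tuned by grid search on the
inner CV (repeated fourfold, ten repeats) minimizing mean MAPE; the outer
simple fourfold CV yields out-of-fold predictions and per-fold MAPE/MAE,
from which the subject's best strategy (lowest mean MAPE) is selected.

Preprocessing is fitted inside each inner training split and on each
outer training fold only, so held-out rows never influence imputation or
scaling statistics.  MAPE denominators are safe because ratings live on
a 1-7 Likert scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, PoissonRegressor
from sklearn.model_selection import KFold, RepeatedKFold
from sklearn.svm import SVR

from . import schema
from .preprocess import FittedPreprocessor, PreprocessPlan, fit_preprocessor

logger = logging.getLogger(__name__)

__all__ = [
    "STRATEGY_ORDER",
    "BASE_STRATEGIES",
    "NestedCVConfig",
    "ModelReport",
    "TunedModel",
    "mape",
    "mae",
    "default_grids",
    "reduced_grids",
    "make_estimator",
    "inner_tune",
    "nested_cv_evaluate",
    "compose_voting",
    "select_best",
    "intercept_only_cv_mape",
    "cohort_statistics",
]

#: Fixed strategy order; also the final tie-break for best-model selection.
STRATEGY_ORDER = ("en", "rf", "gb", "ab", "pr", "sv", "vr")
BASE_STRATEGIES = STRATEGY_ORDER[:-1]

MIN_ROWS = 16  # 4-fold outer CV needs at least 4 rows per fold


@dataclass(frozen=True)
class NestedCVConfig:
    """Nested CV scheme: simple 4-fold outer, repeated 4-fold x 10 inner."""

    outer_folds: int = 4
    inner_folds: int = 4
    inner_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if self.inner_repeats < 1:
            raise ValueError("inner_repeats must be >= 1")


def mape(actual, predicted) -> float:
    """Mean absolute percentage error: (1/n) * sum |(P_k - A_k) / A_k| * 100."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: actual {a.shape} vs predicted {p.shape}")
    if a.size == 0:
        raise ValueError("mape undefined for empty sequences")
    if (a == 0).any():
        raise ValueError("mape undefined: actual contains zeros")
    return float(np.mean(np.abs((p - a) / a)) * 100.0)


def mae(actual, predicted) -> float:
    """Mean absolute error in target units (Likert points)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: actual {a.shape} vs predicted {p.shape}")
    if a.size == 0:
        raise ValueError("mae undefined for empty sequences")
    return float(np.mean(np.abs(p - a)))


# ---------------------------------------------------------------------------
# Strategy factories and hyperparameter grids.


def make_estimator(strategy: str, params: dict, seed: int = 0):
    """Instantiate a strategy's sklearn estimator with given hyperparameters."""
    if strategy == "en":
        return ElasticNet(max_iter=5000, random_state=seed, **params)
    if strategy == "rf":
        return RandomForestRegressor(
            n_estimators=params.get("n_estimators", 60),
            max_depth=params.get("max_depth"),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            random_state=seed,
            n_jobs=1,
        )
    if strategy == "gb":
        return GradientBoostingRegressor(random_state=seed, **params)
    if strategy == "ab":
        return AdaBoostRegressor(random_state=seed, **params)
    if strategy == "pr":
        # Likert ratings 1-7 are valid positive counts; canonical log link.
        return PoissonRegressor(max_iter=1000, **params)
    if strategy == "sv":
        return SVR(**params)
    raise ValueError(f"unknown strategy {strategy!r}")


def default_grids() -> dict[str, list[dict]]:
    """Compact default-centered grids, <= 12 points per strategy."""
    return {
        "en": [
            {"alpha": a, "l1_ratio": r}
            for a in (0.01, 0.1, 1.0)
            for r in (0.2, 0.5, 0.8)
        ],
        "rf": [
            {"max_depth": d, "min_samples_leaf": m}
            for d in (None, 4)
            for m in (1, 3)
        ],
        "gb": [
            {"n_estimators": n, "max_depth": d} for n in (50, 100) for d in (2, 3)
        ],
        "ab": [
            {"n_estimators": n, "learning_rate": lr}
            for n in (25, 50)
            for lr in (0.5, 1.0)
        ],
        "pr": [{"alpha": a} for a in (0.01, 0.1, 1.0)],
        "sv": [
            {"C": c, "epsilon": e} for c in (0.5, 2.0, 8.0) for e in (0.05, 0.2)
        ],
    }


def reduced_grids() -> dict[str, list[dict]]:
    """Single-point grids for fast end-to-end runs (same strategies, no tuning)."""
    return {
        "en": [{"alpha": 0.1, "l1_ratio": 0.5}],
        "rf": [{"max_depth": None, "min_samples_leaf": 1}],
        "gb": [{"n_estimators": 50, "max_depth": 2}],
        "ab": [{"n_estimators": 25, "learning_rate": 1.0}],
        "pr": [{"alpha": 0.1}],
        "sv": [{"C": 2.0, "epsilon": 0.1}],
    }


# ---------------------------------------------------------------------------
# Inner loop: grid search by repeated k-fold MAPE.


@dataclass
class TunedModel:
    strategy: str
    params: dict
    inner_mape: float
    preprocessor: FittedPreprocessor
    estimator: object

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self.preprocessor.transform(table).to_numpy())


def _split_train(table: pd.DataFrame):
    y = table[schema.TARGET].to_numpy(dtype=float)
    X = table.drop(columns=[schema.TARGET])
    return X, y


def _prepare_inner_splits(
    train: pd.DataFrame, config: NestedCVConfig, plan: PreprocessPlan | None
):
    """Fit preprocessing once per inner split; reused across strategies/grids."""
    X, y = _split_train(train)
    rkf = RepeatedKFold(
        n_splits=config.inner_folds,
        n_repeats=config.inner_repeats,
        random_state=config.seed,
    )
    splits = []
    for tr_idx, te_idx in rkf.split(X):
        inner_train = train.iloc[tr_idx]
        pre = fit_preprocessor(inner_train, plan)
        Xtr = pre.transform(inner_train.drop(columns=[schema.TARGET])).to_numpy()
        Xte = pre.transform(X.iloc[te_idx]).to_numpy()
        splits.append((Xtr, y[tr_idx], Xte, y[te_idx]))
    return splits


def inner_tune(
    strategy: str,
    train: pd.DataFrame,
    config: NestedCVConfig,
    grid: list[dict] | None = None,
    plan: PreprocessPlan | None = None,
    splits=None,
    refit_preprocessor: FittedPreprocessor | None = None,
    score_singleton: bool = True,
) -> TunedModel:
    """Grid search minimizing mean inner-CV MAPE; first grid entry wins ties.

    Returns the winning hyperparameters with the estimator refit on the
    whole training table (preprocessing refitted on it too, unless a
    shared ``refit_preprocessor`` fitted on the same table is supplied).
    Selection over a single-point grid is the identity; with
    ``score_singleton=False`` its inner-CV score is skipped (NaN).
    """
    if len(train) < MIN_ROWS:
        raise ValueError(
            f"inner_tune needs >= {MIN_ROWS} rows for {config.inner_folds}-fold CV; "
            f"got {len(train)} -- use fewer folds or more data"
        )
    if grid is None:
        grid = default_grids()[strategy]
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    if len(grid) == 1 and not score_singleton:
        scores = [float("nan")]
        best_idx = 0
    else:
        if splits is None:
            splits = _prepare_inner_splits(train, config, plan)
        scores = []
        for params in grid:
            fold_mapes = []
            for Xtr, ytr, Xte, yte in splits:
                est = make_estimator(strategy, params, seed=config.seed)
                est.fit(Xtr, ytr)
                fold_mapes.append(mape(yte, est.predict(Xte)))
            scores.append(float(np.mean(fold_mapes)))
        # argmin takes the first minimum: ties -> earlier grid entry
        best_idx = int(np.argmin(scores))

    X, y = _split_train(train)
    pre = refit_preprocessor if refit_preprocessor is not None else fit_preprocessor(train, plan)
    est = make_estimator(strategy, grid[best_idx], seed=config.seed)
    est.fit(pre.transform(X).to_numpy(), y)
    return TunedModel(
        strategy=strategy,
        params=grid[best_idx],
        inner_mape=scores[best_idx],
        preprocessor=pre,
        estimator=est,
    )


# ---------------------------------------------------------------------------
# Voting composition and best-model selection.


class VotingPredictor:
    """Unweighted mean of the six tuned base-strategy estimators."""

    def __init__(self, estimators: dict):
        missing = [s for s in BASE_STRATEGIES if s not in estimators]
        if missing:
            raise ValueError(f"voting regressor missing constituents: {missing}")
        self.estimators = {s: estimators[s] for s in BASE_STRATEGIES}

    def predict(self, X) -> np.ndarray:
        return np.mean([est.predict(X) for est in self.estimators.values()], axis=0)


def compose_voting(estimators: dict) -> VotingPredictor:
    """Compose the vr strategy from the six fitted base estimators."""
    return VotingPredictor(estimators)


def select_best(metrics) -> str:
    """Best strategy: lowest mean MAPE, ties by mean MAE, then fixed order.

    ``metrics`` may be a DataFrame indexed by strategy with ``mape_mean``
    and ``mae_mean`` columns, or a mapping strategy -> (mape_mean, mae_mean).
    """
    if isinstance(metrics, pd.DataFrame):
        entries = {
            s: (float(metrics.loc[s, "mape_mean"]), float(metrics.loc[s, "mae_mean"]))
            for s in metrics.index
        }
    else:
        entries = {s: (float(v[0]), float(v[1])) for s, v in metrics.items()}
    order = {s: i for i, s in enumerate(STRATEGY_ORDER)}
    return min(entries, key=lambda s: (entries[s][0], entries[s][1], order.get(s, 99)))


# ---------------------------------------------------------------------------
# Outer loop.


@dataclass
class ModelReport:
    """Per-subject nested-CV outcome for all seven strategies."""

    metrics: pd.DataFrame  # index strategy; mape_mean/std, mae_mean/std (%; points)
    predictions: pd.DataFrame  # timestamp index; actual, fold, <strategy> columns
    best: str
    fold_models: dict[str, list] = field(default_factory=dict, repr=False)
    fold_test_indices: list = field(default_factory=list, repr=False)
    config: NestedCVConfig = field(default_factory=NestedCVConfig)

    def oof(self, strategy: str | None = None) -> pd.DataFrame:
        """Concatenated out-of-fold (actual, predicted) for one strategy."""
        s = strategy or self.best
        return self.predictions[["actual", "fold", s]].rename(columns={s: "predicted"})


def nested_cv_evaluate(
    table: pd.DataFrame,
    config: NestedCVConfig | None = None,
    grids: dict[str, list[dict]] | None = None,
    plan: PreprocessPlan | None = None,
) -> ModelReport:
    """Run the full nested CV over all seven strategies on one feature table.

    ``table`` holds predictor columns plus the ``depression`` target.  For
    each outer fold the six base strategies are tuned on the three
    training folds, refit, and evaluated on the held-out fold; the voting
    regressor is composed per fold from the six tuned estimators and
    evaluated identically.
    """
    if config is None:
        config = NestedCVConfig()
    if len(table) < MIN_ROWS:
        raise ValueError(
            f"nested CV needs >= {MIN_ROWS} rows; got {len(table)} -- "
            "use fewer folds or more data"
        )
    grids = grids or default_grids()
    y_all = table[schema.TARGET].to_numpy(dtype=float)
    if np.unique(y_all).size == 1:
        warnings.warn(
            "target is constant; error metrics are degenerate", stacklevel=2
        )

    outer = KFold(n_splits=config.outer_folds, shuffle=True, random_state=config.seed)
    fold_metrics: dict[str, list[tuple[float, float]]] = {s: [] for s in STRATEGY_ORDER}
    fold_models: dict[str, list] = {s: [] for s in STRATEGY_ORDER}
    fold_test_indices = []
    pred_cols: dict[str, np.ndarray] = {s: np.full(len(table), np.nan) for s in STRATEGY_ORDER}
    fold_of_row = np.full(len(table), -1)

    for fold, (tr_idx, te_idx) in enumerate(outer.split(table)):
        train, test = table.iloc[tr_idx], table.iloc[te_idx]
        X_test = test.drop(columns=[schema.TARGET])
        y_test = y_all[te_idx]
        needs_tuning = any(len(grids[s]) > 1 for s in BASE_STRATEGIES)
        splits = _prepare_inner_splits(train, config, plan) if needs_tuning else None
        fold_pre = fit_preprocessor(train, plan)
        Xte = fold_pre.transform(X_test).to_numpy()

        tuned_estimators = {}
        for s in BASE_STRATEGIES:
            tuned = inner_tune(
                s,
                train,
                config,
                grid=grids[s],
                plan=plan,
                splits=splits,
                refit_preprocessor=fold_pre,
                score_singleton=False,
            )
            tuned_estimators[s] = tuned.estimator
            pred = tuned.estimator.predict(Xte)
            fold_metrics[s].append((mape(y_test, pred), mae(y_test, pred)))
            fold_models[s].append(tuned)
            pred_cols[s][te_idx] = pred

        voter = compose_voting(tuned_estimators)
        vr_pred = voter.predict(Xte)
        fold_metrics["vr"].append((mape(y_test, vr_pred), mae(y_test, vr_pred)))
        fold_models["vr"].append(
            TunedModel("vr", {}, float("nan"), fold_pre, voter)
        )
        pred_cols["vr"][te_idx] = vr_pred
        fold_of_row[te_idx] = fold
        fold_test_indices.append(te_idx)

    rows = []
    for s in STRATEGY_ORDER:
        m = np.array(fold_metrics[s])
        rows.append(
            {
                "strategy": s,
                "mape_mean": m[:, 0].mean(),
                "mape_std": m[:, 0].std(ddof=1),
                "mae_mean": m[:, 1].mean(),
                "mae_std": m[:, 1].std(ddof=1),
            }
        )
    metrics = pd.DataFrame(rows).set_index("strategy")

    predictions = pd.DataFrame(
        {"actual": y_all, "fold": fold_of_row, **pred_cols}, index=table.index
    )
    return ModelReport(
        metrics=metrics,
        predictions=predictions,
        best=select_best(metrics),
        fold_models=fold_models,
        fold_test_indices=fold_test_indices,
        config=config,
    )


def intercept_only_cv_mape(y, config: NestedCVConfig | None = None) -> float:
    """Out-of-fold MAPE of the intercept-only predictor (train-fold mean).

    The null baseline for leakage checks: any genuine model evaluated on
    pure-noise targets should not beat this beyond chance.
    """
    if config is None:
        config = NestedCVConfig()
    y = np.asarray(y, dtype=float)
    outer = KFold(n_splits=config.outer_folds, shuffle=True, random_state=config.seed)
    preds = np.empty_like(y)
    for tr_idx, te_idx in outer.split(y):
        preds[te_idx] = y[tr_idx].mean()
    return mape(y, preds)


# ---------------------------------------------------------------------------
# Cohort-level statistics across subjects.


def _fisher_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(rho) >= 1.0:
        return rho, rho
    z = np.arctanh(rho)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def cohort_statistics(reports: dict[str, ModelReport]) -> dict:
    """Cross-subject summaries mirroring the study's results section.

    Returns per-subject Spearman correlations (best-model out-of-fold
    predictions vs actuals) with Fisher-z 95% CIs, under-/over-estimation
    percentages (predictions rounded to the Likert scale before
    comparison) with a signed-rank test, and the paired t-test of
    best-model vs voting-regressor MAPE.
    """
    from .synthetic import discretize_mood

    if not reports:
        raise ValueError("cohort_statistics needs at least one subject report")
    per_subject = []
    for sid, rep in reports.items():
        oof = rep.oof()
        actual = oof["actual"].to_numpy()
        predicted = oof["predicted"].to_numpy()
        if np.unique(actual).size < 2 or np.unique(predicted).size < 2:
            rho, pval = np.nan, np.nan
        else:
            rho, pval = stats.spearmanr(actual, predicted)
        lo, hi = _fisher_ci(rho, len(actual)) if np.isfinite(rho) else (np.nan, np.nan)
        rounded = discretize_mood(predicted)
        per_subject.append(
            {
                "subject": sid,
                "best": rep.best,
                "best_mape": float(rep.metrics.loc[rep.best, "mape_mean"]),
                "vr_mape": float(rep.metrics.loc["vr", "mape_mean"]),
                "spearman_rho": rho,
                "rho_p": pval,
                "rho_ci_low": lo,
                "rho_ci_high": hi,
                "pct_under": float(np.mean(rounded < actual) * 100),
                "pct_over": float(np.mean(rounded > actual) * 100),
            }
        )
    df = pd.DataFrame(per_subject).set_index("subject")

    out: dict = {"per_subject": df}
    if len(df) >= 2:
        diffs = df["best_mape"] - df["vr_mape"]
        if np.allclose(diffs, 0):
            logger.warning("best == vr for every subject; paired t reported as 0")
            out["best_vs_vr_t"] = 0.0
            out["best_vs_vr_p"] = 1.0
        else:
            t, p = stats.ttest_rel(df["best_mape"], df["vr_mape"])
            out["best_vs_vr_t"] = float(t)
            out["best_vs_vr_p"] = float(p)
        ud = df["pct_under"] - df["pct_over"]
        if np.allclose(ud, 0):
            out["under_over_p"] = 1.0
        else:
            try:
                out["under_over_p"] = float(stats.wilcoxon(ud).pvalue)
            except ValueError:
                out["under_over_p"] = np.nan
    else:
        logger.warning("paired best-vs-vr test needs >= 2 subjects; skipped")
    out["mean_pct_under"] = float(df["pct_under"].mean())
    out["mean_pct_over"] = float(df["pct_over"].mean())
    return out
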