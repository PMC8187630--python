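"""Leakage-safe preprocessing: imputation, encoding, max-abs scaling.

The 43 predictors are processed in three disjoint groups:

* discrete (time of day): most-frequent-class imputation, then ordinal
  integer codes 0..n_categories-1;
* continuous watch + EMA variables: round-robin multivariate regression
  imputation (MICE-style) -- each column with missing cells is modeled as
  a ridge regression on all other columns, cycling columns for a fixed
  number of rounds, overwriting only originally-missing cells;
* continuous neurocognitive variables: constant imputation (fill 0) --
  session-level scalars are too coarse (3 distinct values per subject)
  to support regression imputation.

All continuous columns are then divided by their per-column maximum
absolute value learned from the training table (no centering, so exact
zeros -- and thereby sparsity -- are preserved).  Fit learns statistics
from the training table only; transform never recomputes them, so
test-fold edits cannot leak into a fitted object.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessPlan",
    "RoundRobinImputer",
    "iterative_impute",
    "FittedPreprocessor",
    "fit_preprocessor",
]

#: Ridge penalty for per-column imputation regressions; near-OLS, the tiny
#: penalty only guards against exact collinearity.
RIDGE_ALPHA = 1e-6


def _ridge_fit(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge with unpenalized intercept (centered normal equations)."""
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    A = Xc.T @ Xc
    A[np.diag_indices_from(A)] += alpha
    coef = np.linalg.solve(A, Xc.T @ (y - y_mean))
    return coef, float(y_mean - x_mean @ coef)


@dataclass(frozen=True)
class PreprocessPlan:
    """Column grouping and imputer/scaler settings.

    The three groups must partition the predictor columns of the tables
    the plan is fitted on.
    """

    discrete: tuple[str, ...] = schema.DISCRETE_COLUMNS
    continuous_watch_ema: tuple[str, ...] = schema.WATCH_EMA_COLUMNS
    continuous_neurocog: tuple[str, ...] = schema.NEUROCOG_COLUMNS
    n_iterations: int = 10
    constant_fill: float = 0.0
    categories: dict = field(
        default_factory=lambda: {"time_of_day": list(schema.TIME_OF_DAY_BINS)}
    )

    def __post_init__(self) -> None:
        groups = [set(self.discrete), set(self.continuous_watch_ema),
                  set(self.continuous_neurocog)]
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != len(union):
            dupes = sorted(
                c for c in union
                if sum(c in g for g in groups) > 1
            )
            raise ValueError(f"column groups must be disjoint; duplicated: {dupes}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def columns(self) -> tuple[str, ...]:
        return self.discrete + self.continuous_watch_ema + self.continuous_neurocog

    @classmethod
    def for_columns(cls, columns, **kwargs) -> "PreprocessPlan":
        """Plan for an arbitrary predictor set: schema columns keep their
        pinned group, unknown columns are treated as continuous watch/EMA."""
        disc, watch, neuro = [], [], []
        for c in columns:
            if c in schema.DISCRETE_COLUMNS:
                disc.append(c)
            elif c in schema.NEUROCOG_COLUMNS:
                neuro.append(c)
            else:
                watch.append(c)
        return cls(
            discrete=tuple(disc),
            continuous_watch_ema=tuple(watch),
            continuous_neurocog=tuple(neuro),
            **kwargs,
        )


class RoundRobinImputer:
    """Deterministic MICE-style imputer with ridge column regressions.

    Fit: initialize missing cells with column means; for ``n_iterations``
    rounds, visit columns in ascending-missingness order (stable in
    column index) and regress each column on all others using the rows
    where it was originally observed, overwriting only originally-missing
    cells with the predictions.  Transform replays the fitted round
    regressors on new data (initialized with the training means) without
    refitting anything.
    """

    def __init__(self, n_iterations: int = 10, alpha: float = RIDGE_ALPHA):
        self.n_iterations = n_iterations
        self.alpha = alpha

    def fit_transform(self, X: np.ndarray, column_names=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("iterative imputation needs a 2-D matrix with >= 2 columns")
        n, p = X.shape
        mask = np.isnan(X)
        fully_missing = np.flatnonzero(mask.all(axis=0))
        if fully_missing.size:
            names = (
                [column_names[i] for i in fully_missing]
                if column_names is not None
                else list(fully_missing)
            )
            raise ValueError(f"column(s) fully missing, cannot impute: {names}")
        self.means_ = np.nanmean(X, axis=0)
        # Ascending missingness, ties by column index (np.argsort is stable).
        self.order_ = np.argsort(mask.sum(axis=0), kind="stable")
        self.models_: list[list[tuple[np.ndarray, float]]] = []

        Xc = np.where(mask, self.means_, X)
        others = {j: np.delete(np.arange(p), j) for j in range(p)}
        for _ in range(self.n_iterations):
            round_models = []
            for j in self.order_:
                obs = ~mask[:, j]
                coef, intercept = _ridge_fit(Xc[obs][:, others[j]], X[obs, j], self.alpha)
                round_models.append((coef, intercept))
                if mask[:, j].any():
                    Xc[mask[:, j], j] = Xc[mask[:, j]][:, others[j]] @ coef + intercept
            self.models_.append(round_models)
        return Xc

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p != len(self.means_):
            raise ValueError("column count differs from fit")
        mask = np.isnan(X)
        Xc = np.where(mask, self.means_, X)
        if not mask.any():
            return Xc
        others = {j: np.delete(np.arange(p), j) for j in range(p)}
        for round_models in self.models_:
            for j, (coef, intercept) in zip(self.order_, round_models):
                if mask[:, j].any():
                    Xc[mask[:, j], j] = Xc[mask[:, j]][:, others[j]] @ coef + intercept
        return Xc

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "alpha": self.alpha,
            "means": self.means_.tolist(),
            "order": self.order_.tolist(),
            "models": [
                [[coef.tolist(), intercept] for coef, intercept in round_models]
                for round_models in self.models_
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoundRobinImputer":
        imp = cls(n_iterations=d["n_iterations"], alpha=d["alpha"])
        imp.means_ = np.asarray(d["means"], dtype=float)
        imp.order_ = np.asarray(d["order"], dtype=int)
        imp.models_ = [
            [(np.asarray(coef, dtype=float), float(intercept)) for coef, intercept in rm]
            for rm in d["models"]
        ]
        return imp


def iterative_impute(matrix, n_iterations: int = 10, column_names=None) -> np.ndarray:
    """Functional one-shot round-robin imputation of a matrix with NaNs."""
    return RoundRobinImputer(n_iterations=n_iterations).fit_transform(
        matrix, column_names=column_names
    )


class FittedPreprocessor:
    """Learned per-column statistics; transform applies them without refit."""

    def __init__(self, plan: PreprocessPlan):
        self.plan = plan

    # -- fitting -----------------------------------------------------------

    def fit(self, train: pd.DataFrame) -> "FittedPreprocessor":
        if len(train) == 0:
            raise ValueError("cannot fit a preprocessor on an empty table")
        missing = [c for c in self.plan.columns if c not in train.columns]
        if missing:
            raise ValueError(f"training table missing plan columns: {missing}")
        self.columns_ = list(self.plan.columns)

        self.category_maps_: dict[str, dict[str, int]] = {}
        self.most_frequent_: dict[str, str] = {}
        for col in self.plan.discrete:
            cats = self.plan.categories.get(col)
            if cats is None:
                cats = sorted(train[col].dropna().astype(str).unique())
            self.category_maps_[col] = {c: i for i, c in enumerate(cats)}
            observed = train[col].dropna().astype(str)
            observed = observed[observed.isin(cats)]
            if len(observed):
                counts = observed.value_counts()
                top = counts.max()
                # Deterministic mode: among ties, first in category order.
                self.most_frequent_[col] = next(
                    c for c in cats if counts.get(c, 0) == top
                )
            else:
                self.most_frequent_[col] = cats[0]

        self.imputer_ = None
        if self.plan.continuous_watch_ema:
            self.imputer_ = RoundRobinImputer(n_iterations=self.plan.n_iterations)
            watch = self.imputer_.fit_transform(
                train[list(self.plan.continuous_watch_ema)].to_numpy(dtype=float),
                column_names=list(self.plan.continuous_watch_ema),
            )
        else:
            watch = np.empty((len(train), 0))

        neuro = (
            train[list(self.plan.continuous_neurocog)]
            .to_numpy(dtype=float)
            .copy()
        )
        neuro[np.isnan(neuro)] = self.plan.constant_fill

        self.max_abs_: dict[str, float] = {}
        for block, cols in (
            (watch, self.plan.continuous_watch_ema),
            (neuro, self.plan.continuous_neurocog),
        ):
            for i, col in enumerate(cols):
                m = float(np.max(np.abs(block[:, i]))) if len(block) else 0.0
                self.max_abs_[col] = m if m > 0 else 1.0

        self.fingerprint_ = int(
            pd.util.hash_pandas_object(
                train[self.columns_].astype(str), index=False
            ).sum()
            & 0x7FFFFFFF
        )
        return self

    # -- transforming ------------------------------------------------------

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns_ if c not in table.columns]
        if missing:
            raise ValueError(f"table missing fitted schema columns: {missing}")
        out: dict[str, np.ndarray] = {}

        for col in self.plan.discrete:
            cmap = self.category_maps_[col]
            fallback = cmap[self.most_frequent_[col]]
            vals = table[col].astype(object)
            codes = np.empty(len(table), dtype=float)
            unseen = 0
            for i, v in enumerate(vals):
                if pd.isna(v):
                    codes[i] = fallback
                elif str(v) in cmap:
                    codes[i] = cmap[str(v)]
                else:
                    codes[i] = fallback
                    unseen += 1
            if unseen:
                logger.warning(
                    "%d unseen %r categories mapped to most-frequent training class",
                    unseen,
                    col,
                )
            out[col] = codes

        if self.plan.continuous_watch_ema:
            watch = self.imputer_.transform(
                table[list(self.plan.continuous_watch_ema)].to_numpy(dtype=float)
            )
            for i, col in enumerate(self.plan.continuous_watch_ema):
                out[col] = watch[:, i] / self.max_abs_[col]

        if self.plan.continuous_neurocog:
            neuro = table[list(self.plan.continuous_neurocog)].to_numpy(dtype=float).copy()
            neuro[np.isnan(neuro)] = self.plan.constant_fill
            for i, col in enumerate(self.plan.continuous_neurocog):
                out[col] = neuro[:, i] / self.max_abs_[col]

        return pd.DataFrame(out, index=table.index)[self.columns_]

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "plan": {
                    "discrete": list(self.plan.discrete),
                    "continuous_watch_ema": list(self.plan.continuous_watch_ema),
                    "continuous_neurocog": list(self.plan.continuous_neurocog),
                    "n_iterations": self.plan.n_iterations,
                    "constant_fill": self.plan.constant_fill,
                    "categories": self.plan.categories,
                },
                "category_maps": self.category_maps_,
                "most_frequent": self.most_frequent_,
                "max_abs": self.max_abs_,
                "imputer": self.imputer_.to_dict() if self.imputer_ else None,
                "fingerprint": self.fingerprint_,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "FittedPreprocessor":
        d = json.loads(payload)
        plan = PreprocessPlan(
            discrete=tuple(d["plan"]["discrete"]),
            continuous_watch_ema=tuple(d["plan"]["continuous_watch_ema"]),
            continuous_neurocog=tuple(d["plan"]["continuous_neurocog"]),
            n_iterations=d["plan"]["n_iterations"],
            constant_fill=d["plan"]["constant_fill"],
            categories=d["plan"]["categories"],
        )
        obj = cls(plan)
        obj.columns_ = list(plan.columns)
        obj.category_maps_ = {
            col: {k: int(v) for k, v in cmap.items()}
            for col, cmap in d["category_maps"].items()
        }
        obj.most_frequent_ = d["most_frequent"]
        obj.max_abs_ = {k: float(v) for k, v in d["max_abs"].items()}
        obj.imputer_ = (
            RoundRobinImputer.from_dict(d["imputer"]) if d["imputer"] else None
        )
        obj.fingerprint_ = d["fingerprint"]
        return obj


def fit_preprocessor(train: pd.DataFrame, plan: PreprocessPlan | None = None) -> FittedPreprocessor:
    """Fit the grouped imputation/encoding/scaling transformer on a table."""
    if plan is None:
        predictors = [c for c in train.columns if c != schema.TARGET]
        if set(predictors) == set(schema.FEATURES):
            plan = PreprocessPlan()
        else:
            plan = PreprocessPlan.for_columns(predictors)
    return FittedPreprocessor(plan).fit(train)
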