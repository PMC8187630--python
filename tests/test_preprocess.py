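"""Imputation, encoding and scaling: correctness and leakage safety."""

import numpy as np
import pandas as pd
import pytest

from pmhm import schema
from pmhm.preprocess import (
    FittedPreprocessor,
    PreprocessPlan,
    fit_preprocessor,
    iterative_impute,
)


class TestIterativeImpute:
    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        assert np.array_equal(iterative_impute(X), X)

    def test_collinear_recovery(self):
        """A missing cell in y = 2x is recovered exactly by the regression."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        X = np.column_stack([x, 2 * x])
        X[7, 1] = np.nan
        out = iterative_impute(X)
        assert out[7, 1] == pytest.approx(2 * x[7], abs=1e-6)

    def test_constant_column_filled_with_constant(self):
        X = np.column_stack([np.arange(20.0), np.full(20, 3.5)])
        X[4, 1] = np.nan
        out = iterative_impute(X)
        assert out[4, 1] == pytest.approx(3.5, abs=1e-8)

    def test_fully_missing_column_named_in_error(self):
        X = np.ones((10, 3))
        X[:, 2] = np.nan
        with pytest.raises(ValueError, match="colC"):
            iterative_impute(X, column_names=["colA", "colB", "colC"])

    def test_matches_sklearn_iterative_imputer(self):
        """Independent cross-check against sklearn's chained-equations imputer."""
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(2)
        cov = np.array([[1.0, 0.7, 0.3], [0.7, 1.0, 0.5], [0.3, 0.5, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=120)
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        ours = iterative_impute(Xm, n_iterations=10)
        ref = IterativeImputer(
            estimator=Ridge(alpha=1e-6),
            max_iter=10,
            tol=1e-9,
            imputation_order="ascending",
            initial_strategy="mean",
            sample_posterior=False,
            random_state=0,
        ).fit_transform(Xm)
        assert np.allclose(ours, ref, atol=5e-3)

    def test_mcar_preserves_column_means(self):
        """10% MCAR deletion: post-imputation mean shift <= 0.05 column sd."""
        rng = np.random.default_rng(3)
        p = 6
        A = rng.normal(size=(p, p))
        cov = A @ A.T / p + np.eye(p)
        X = rng.multivariate_normal(np.zeros(p), cov, size=300)
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        out = iterative_impute(Xm)
        shift = np.abs(out.mean(axis=0) - X.mean(axis=0))
        assert (shift <= 0.05 * X.std(axis=0)).all()


def _toy_table(n=24, seed=0, with_missing=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "time_of_day": rng.choice(list(schema.TIME_OF_DAY_BINS), n),
            "a": rng.normal(2, 1, n),
            "b": rng.normal(-1, 2, n),
            "sparse": np.where(rng.random(n) < 0.8, 0.0, rng.normal(5, 1, n)),
            "neuro": rng.normal(0, 1, n),
        }
    )
    if with_missing:
        df.loc[df.index[3], "a"] = np.nan
        df.loc[df.index[5], "neuro"] = np.nan
        df.loc[df.index[7], "time_of_day"] = np.nan
    return df


def _toy_plan():
    return PreprocessPlan(
        discrete=("time_of_day",),
        continuous_watch_ema=("a", "b", "sparse"),
        continuous_neurocog=("neuro",),
    )


class TestFittedPreprocessor:
    def test_train_output_in_unit_interval(self):
        df = _toy_table()
        pre = fit_preprocessor(df, _toy_plan())
        out = pre.transform(df)
        for col in ("a", "b", "sparse", "neuro"):
            assert out[col].abs().max() <= 1.0 + 1e-12

    def test_zero_column_scale_one(self):
        df = _toy_table(with_missing=False)
        df["sparse"] = 0.0
        pre = fit_preprocessor(df, _toy_plan())
        assert pre.max_abs_["sparse"] == 1.0
        assert (pre.transform(df)["sparse"] == 0.0).all()

    def test_sparsity_preserved(self):
        """Max-abs scaling never shifts data, so exact zeros stay zero."""
        df = _toy_table(with_missing=False)
        pre = fit_preprocessor(df, _toy_plan())
        out = pre.transform(df)
        assert ((df["sparse"] == 0.0) == (out["sparse"] == 0.0)).all()

    def test_transform_is_deterministic_and_rowwise(self):
        df = _toy_table()
        pre = fit_preprocessor(df, _toy_plan())
        test = _toy_table(seed=9, with_missing=False)
        base = pre.transform(test)
        pd.testing.assert_frame_equal(base, pre.transform(test))
        # Editing one held-out row leaves every other transformed row alone.
        edited = test.copy()
        edited.loc[edited.index[0], "b"] = 99.0
        out = pre.transform(edited)
        pd.testing.assert_frame_equal(base.iloc[1:], out.iloc[1:])

    def test_no_clipping_on_test_data(self):
        df = _toy_table(with_missing=False)
        pre = fit_preprocessor(df, _toy_plan())
        test = df.copy()
        test.loc[test.index[0], "a"] = df["a"].abs().max() * 10
        assert pre.transform(test)["a"].abs().max() > 1.0

    def test_unseen_category_maps_to_mode(self, caplog):
        import logging

        df = _toy_table()
        plan = PreprocessPlan(
            discrete=("time_of_day",),
            continuous_watch_ema=("a", "b", "sparse"),
            continuous_neurocog=("neuro",),
            categories={"time_of_day": ["bin1", "bin2"]},
        )
        df["time_of_day"] = np.where(np.arange(len(df)) % 3 == 0, "bin1", "bin2")
        pre = fit_preprocessor(df, plan)
        test = df.copy()
        test.loc[test.index[0], "time_of_day"] = "binX"
        with caplog.at_level(logging.WARNING, logger="pmhm.preprocess"):
            out = pre.transform(test)
        assert out["time_of_day"].iloc[0] == pre.category_maps_["time_of_day"][
            pre.most_frequent_["time_of_day"]
        ]
        assert "unseen" in caplog.text

    def test_fit_statistics_ignore_test_tables(self):
        """Leakage guard: a fitted object is a function of its train table only."""
        df = _toy_table()
        pre = fit_preprocessor(df, _toy_plan())
        snapshot = pre.to_json()
        wild = _toy_table(seed=77)
        wild.loc[:, "a"] = 1e9
        pre.transform(wild)
        assert pre.to_json() == snapshot

    def test_neurocog_constant_fill(self):
        df = _toy_table()
        pre = fit_preprocessor(df, _toy_plan())
        out = pre.transform(df)
        assert out["neuro"].iloc[5] == 0.0

    def test_json_roundtrip(self):
        df = _toy_table()
        pre = fit_preprocessor(df, _toy_plan())
        clone = FittedPreprocessor.from_json(pre.to_json())
        test = _toy_table(seed=4)
        pd.testing.assert_frame_equal(pre.transform(test), clone.transform(test))

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            PreprocessPlan(
                discrete=("a",),
                continuous_watch_ema=("a", "b"),
                continuous_neurocog=(),
            )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_preprocessor(_toy_table().iloc[:0], _toy_plan())


def test_default_plan_covers_schema(feature_table):
    pre = fit_preprocessor(feature_table)
    out = pre.transform(feature_table.drop(columns=[schema.TARGET]))
    assert list(out.columns) == list(schema.FEATURES)
    cont = [c for c in schema.FEATURES if c not in schema.DISCRETE_COLUMNS]
    assert out[cont].abs().max().max() <= 1.0 + 1e-12
    assert not out.isna().any().any()
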