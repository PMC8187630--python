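"""MAPE/MAE, inner tuning, nested CV, voting and best-model selection."""

import numpy as np
import pandas as pd
import pytest

from pmhm import schema
from pmhm.models import (
    ModelReport,
    NestedCVConfig,
    compose_voting,
    inner_tune,
    intercept_only_cv_mape,
    mae,
    mape,
    nested_cv_evaluate,
    reduced_grids,
    select_best,
    cohort_statistics,
)

from conftest import make_linear_table

FAST_CV = NestedCVConfig(inner_repeats=2, seed=0)


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "actual,predicted,expected",
        [
            ([3, 4, 5], [3, 4, 5], 0.0),
            ([2], [1], 50.0),
            ([1, 2, 4], [2, 1, 5], (100 + 50 + 25) / 3),
        ],
    )
    def test_mape_examples(self, actual, predicted, expected):
        assert mape(actual, predicted) == pytest.approx(expected)

    def test_mape_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            mape([1, 2], [1])
        with pytest.raises(ValueError, match="zero"):
            mape([0, 1], [1, 1])

    def test_mae(self):
        assert mae([1, 3], [2, 5]) == pytest.approx(1.5)


class TestInnerTune:
    def test_singleton_grid_returned_with_score(self):
        table = make_linear_table(n=40, noise_sd=0.3, seed=1)
        grid = [{"alpha": 0.1, "l1_ratio": 0.5}]
        tuned = inner_tune("en", table, FAST_CV, grid=grid)
        assert tuned.params == grid[0]
        assert np.isfinite(tuned.inner_mape) and tuned.inner_mape >= 0

    def test_duplicate_entries_first_wins(self):
        table = make_linear_table(n=40, noise_sd=0.3, seed=1)
        grid = [{"alpha": 0.1, "l1_ratio": 0.5}, {"alpha": 0.1, "l1_ratio": 0.5}]
        tuned = inner_tune("en", table, FAST_CV, grid=grid)
        assert tuned.params is grid[0]

    def test_noiseless_linear_prefers_small_penalty(self):
        """A huge elastic-net penalty collapses to the intercept and loses."""
        table = make_linear_table(n=48, betas=[2, 0, 0, 0, 0], noise_sd=0.0, seed=2)
        grid = [{"alpha": 1e4, "l1_ratio": 0.5}, {"alpha": 1e-3, "l1_ratio": 0.5}]
        tuned = inner_tune("en", table, FAST_CV, grid=grid)
        assert tuned.params["alpha"] == 1e-3

    def test_too_few_rows(self):
        table = make_linear_table(n=10)
        with pytest.raises(ValueError, match="fewer folds"):
            inner_tune("en", table, FAST_CV)


class TestNestedCV:
    def test_constant_target_near_zero_error(self):
        table = make_linear_table(n=32, betas=[0] * 5, noise_sd=0.0, seed=3)
        table[schema.TARGET] = 4.0
        with pytest.warns(UserWarning, match="constant"):
            report = nested_cv_evaluate(table, config=FAST_CV, grids=reduced_grids())
        assert (report.metrics["mape_mean"] < 1.0).all()

    def test_metrics_match_bruteforce_recomputation(self):
        """Reported MAPE/MAE equal a from-scratch recomputation from stored
        out-of-fold predictions, per strategy and fold."""
        table = make_linear_table(n=40, noise_sd=0.5, seed=4)
        report = nested_cv_evaluate(table, config=FAST_CV, grids=reduced_grids())
        for s in report.metrics.index:
            fold_mapes, fold_maes = [], []
            for f in sorted(report.predictions["fold"].unique()):
                sub = report.predictions[report.predictions["fold"] == f]
                a, p = sub["actual"].to_numpy(), sub[s].to_numpy()
                fold_mapes.append(np.mean(np.abs((p - a) / a)) * 100)
                fold_maes.append(np.mean(np.abs(p - a)))
            assert report.metrics.loc[s, "mape_mean"] == pytest.approx(
                np.mean(fold_mapes), abs=1e-10
            )
            assert report.metrics.loc[s, "mae_mean"] == pytest.approx(
                np.mean(fold_maes), abs=1e-10
            )

    def test_best_never_worse_than_vr(self):
        table = make_linear_table(n=40, noise_sd=0.5, seed=5)
        report = nested_cv_evaluate(table, config=FAST_CV, grids=reduced_grids())
        assert (
            report.metrics.loc[report.best, "mape_mean"]
            <= report.metrics.loc["vr", "mape_mean"]
        )

    def test_every_row_predicted_once(self):
        table = make_linear_table(n=40, noise_sd=0.5, seed=6)
        report = nested_cv_evaluate(table, config=FAST_CV, grids=reduced_grids())
        assert not report.predictions[list(report.metrics.index)].isna().any().any()
        assert set(report.predictions["fold"]) == set(range(4))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="fewer folds"):
            nested_cv_evaluate(make_linear_table(n=12), config=FAST_CV)


class TestVoting:
    class _Const:
        def __init__(self, c):
            self.c = c

        def predict(self, X):
            return np.full(len(X), self.c)

    def test_mean_of_constituents(self):
        ests = {s: self._Const(3.0) for s in ("en", "rf", "gb", "ab", "pr", "sv")}
        vr = compose_voting(ests)
        assert np.allclose(vr.predict(np.zeros((4, 2))), 3.0)
        ests["en"] = self._Const(1.0)
        ests["rf"] = self._Const(7.0)
        for s in ("gb", "ab", "pr", "sv"):
            ests[s] = self._Const(4.0)
        assert np.allclose(compose_voting(ests).predict(np.zeros((2, 2))), 4.0)

    def test_missing_constituent_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compose_voting({"en": self._Const(1.0)})


class TestSelectBest:
    # Printed per-strategy summaries for two subjects of the study cohort.
    P1 = {
        "ab": (10.07, 0.449), "en": (11.89, 0.528), "gb": (10.35, 0.477),
        "pr": (11.90, 0.529), "rf": (9.61, 0.440), "sv": (7.55, 0.358),
        "vr": (9.86, 0.447),
    }
    P14 = {
        "ab": (46.75, 1.063), "en": (55.68, 1.264), "gb": (53.03, 1.122),
        "pr": (71.25, 1.458), "rf": (40.88, 1.007), "sv": (62.51, 1.326),
        "vr": (42.73, 0.979),
    }

    def test_published_rows(self):
        assert select_best(self.P1) == "sv"
        assert select_best(self.P14) == "rf"

    def test_all_tied_fixed_order(self):
        tied = {s: (10.0, 0.5) for s in ("en", "rf", "gb", "ab", "pr", "sv", "vr")}
        assert select_best(tied) == "en"

    def test_mae_breaks_mape_ties(self):
        metrics = {"en": (10.0, 0.6), "rf": (10.0, 0.4), "sv": (11.0, 0.1)}
        assert select_best(metrics) == "rf"


def _fake_report(predicted, actual, best="en"):
    n = len(actual)
    metrics = pd.DataFrame(
        {"mape_mean": [10.0, 12.0], "mape_std": [1, 1],
         "mae_mean": [0.5, 0.6], "mae_std": [0.1, 0.1]},
        index=pd.Index([best, "vr"], name="strategy"),
    )
    preds = pd.DataFrame(
        {"actual": actual, "fold": np.zeros(n, dtype=int), best: predicted,
         "vr": predicted},
    )
    return ModelReport(metrics=metrics, predictions=preds, best=best)


class TestCohortStatistics:
    def test_monotone_predictions_give_rho_one(self):
        actual = np.array([1, 2, 3, 4, 5, 6, 7, 6, 5, 4], dtype=float)
        rep = _fake_report(actual * 0.9 + 0.2, actual)
        out = cohort_statistics({"s1": rep, "s2": rep})
        row = out["per_subject"].loc["s1"]
        assert row["spearman_rho"] == pytest.approx(1.0)
        assert row["rho_ci_high"] == pytest.approx(1.0)

    def test_antitone_predictions_give_rho_minus_one(self):
        actual = np.arange(1, 11, dtype=float)
        rep = _fake_report(-actual, actual)
        out = cohort_statistics({"s1": rep, "s2": rep})
        assert out["per_subject"].loc["s1", "spearman_rho"] == pytest.approx(-1.0)

    def test_identical_best_and_vr_yields_zero_t(self):
        actual = np.arange(1, 11, dtype=float)
        rep = _fake_report(actual, actual)
        rep.metrics.loc["vr", "mape_mean"] = rep.metrics.loc["en", "mape_mean"]
        out = cohort_statistics({"s1": rep, "s2": rep})
        assert out["best_vs_vr_t"] == 0.0


def test_intercept_only_baseline_positive():
    y = np.array([2, 3, 4, 5, 3, 4, 2, 6] * 4, dtype=float)
    assert intercept_only_cv_mape(y, FAST_CV) > 0
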