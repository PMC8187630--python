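"""End-to-end per-subject pipeline: extract -> fit -> explain -> report.

Subjects are processed independently and serially; the whole run is a
pure function of (input files, config, seed).  Each subject emits three
reports: a performance report (per-strategy MAPE/MAE across outer
folds), a prediction report (out-of-fold actual vs predicted), and a
feature-importance report (per-instance Shapley values plus the top-k
ranking).

Two known single-subject failure modes are guarded: subjects with fewer
than 16 answered EMAs are skipped with a warning (too little data for
4-fold nested CV), and subjects whose ratings are >= 90% a single value
are flagged for insufficient variability (modeling still proceeds).
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import schema
from .features import build_feature_table, read_subject, write_features
from .models import (
    MIN_ROWS,
    ModelReport,
    NestedCVConfig,
    cohort_statistics,
    default_grids,
    nested_cv_evaluate,
    reduced_grids,
)
from .preprocess import PreprocessPlan
from .shapley import domain_frequencies, explain_report, rank_and_summarize

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "UserError", "run_pipeline", "run_subject"]


class UserError(ValueError):
    """A problem the operator can fix (bad config, unreadable input)."""


_ALLOWED_KEYS = {
    "seed",
    "log_level",
    "simulate",
    "preprocess",
    "cv",
    "grids",
    "shap",
    "low_variability_threshold",
}
_ALLOWED_SIMULATE = {
    "n_subjects",
    "n_days",
    "ema_times",
    "completion_prob",
    "baseline_mood",
    "ar_coefficient",
    "noise_sd",
    "anxiety_noise_sd",
    "effects",
    "start_date",
}
_ALLOWED_PREPROCESS = {"n_iterations", "constant_fill"}
_ALLOWED_CV = {"outer_folds", "inner_folds", "inner_repeats"}
_ALLOWED_SHAP = {"n_permutations", "background_cap", "max_instances", "top_k"}


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    cv: NestedCVConfig = field(default_factory=NestedCVConfig)
    grids: dict | str = "full"
    shap: dict = field(default_factory=dict)
    low_variability_threshold: float = 0.9

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise UserError("pipeline config must be a mapping")
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise UserError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in (
            ("simulate", _ALLOWED_SIMULATE),
            ("preprocess", _ALLOWED_PREPROCESS),
            ("cv", _ALLOWED_CV),
            ("shap", _ALLOWED_SHAP),
        ):
            extra = set(raw.get(section, {}) or {}) - allowed
            if extra:
                raise UserError(f"unknown keys under {section!r}: {sorted(extra)}")
        seed = int(raw.get("seed", 0))
        cv = NestedCVConfig(seed=seed, **(raw.get("cv", {}) or {}))
        grids = raw.get("grids", "full")
        if isinstance(grids, str) and grids not in ("full", "reduced"):
            raise UserError("grids must be 'full', 'reduced', or an explicit mapping")
        return cls(
            seed=seed,
            log_level=str(raw.get("log_level", "INFO")),
            simulate=raw.get("simulate", {}) or {},
            preprocess=raw.get("preprocess", {}) or {},
            cv=cv,
            grids=grids,
            shap=raw.get("shap", {}) or {},
            low_variability_threshold=float(raw.get("low_variability_threshold", 0.9)),
        )

    def resolved_grids(self) -> dict:
        if self.grids == "full":
            return default_grids()
        if self.grids == "reduced":
            return reduced_grids()
        return {s: list(g) for s, g in self.grids.items()}

    def plan(self) -> PreprocessPlan:
        return PreprocessPlan(**self.preprocess)


def _check_variability(table, subject_id: str, threshold: float) -> None:
    counts = table[schema.TARGET].value_counts(normalize=True)
    if counts.iloc[0] >= threshold:
        logger.warning(
            "subject %s: %.0f%% of ratings are the single value %s -- "
            "insufficient variability, model fit may be inadequate",
            subject_id,
            counts.iloc[0] * 100,
            counts.index[0],
        )


def run_subject(
    config: PipelineConfig, subject_dir: Path, out_dir: Path
) -> ModelReport | None:
    """Run extract/fit/explain for one subject directory; None if skipped."""
    subject_id = subject_dir.name
    out = Path(out_dir) / subject_id
    stage = "extract"
    try:
        subject = read_subject(subject_dir)
        table = build_feature_table(subject)
        if len(table) < MIN_ROWS:
            logger.warning(
                "subject %s skipped: only %d answered EMAs (< %d needed for "
                "4-fold nested CV)",
                subject_id,
                len(table),
                MIN_ROWS,
            )
            return None
        _check_variability(table, subject_id, config.low_variability_threshold)
        out.mkdir(parents=True, exist_ok=True)
        write_features(table, out / "features.csv")

        stage = "fit"
        report = nested_cv_evaluate(
            table,
            config=config.cv,
            grids=config.resolved_grids(),
            plan=config.plan(),
        )
        perf = report.metrics.reset_index()
        perf.insert(0, "subject", subject_id)
        perf.to_csv(out / "performance_report.csv", index=False)
        preds = report.oof().reset_index()
        preds.to_csv(out / "predictions.csv", index=False)
        (out / "best_model.json").write_text(
            json.dumps(
                {
                    "subject": subject_id,
                    "best": report.best,
                    "mape_mean": float(report.metrics.loc[report.best, "mape_mean"]),
                    "mae_mean": float(report.metrics.loc[report.best, "mae_mean"]),
                    "params_per_fold": [
                        t.params for t in report.fold_models[report.best]
                    ],
                },
                indent=1,
            )
        )

        stage = "explain"
        shap_cfg = config.shap
        shap_df = explain_report(
            report,
            table,
            n_permutations=int(shap_cfg.get("n_permutations", 200)),
            background_cap=int(shap_cfg.get("background_cap", 100)),
            max_instances=shap_cfg.get("max_instances"),
            seed=config.seed,
        )
        shap_df.to_csv(out / "shap_report.csv", index=True)
        ranking = rank_and_summarize(shap_df, k=int(shap_cfg.get("top_k", 5)))
        top = ranking.table[ranking.table["top_k"]]
        signs = {
            f: float(shap_df[f].mean()) for f in top.index
        }
        (out / "top_features.json").write_text(
            json.dumps(
                {
                    "subject": subject_id,
                    "top_features": [
                        {
                            "feature": f,
                            "mean_abs_phi": float(top.loc[f, "mean_abs_phi"]),
                            "rank": int(top.loc[f, "rank"]),
                            "mean_phi": signs[f],
                            "domain": schema.FEATURE_DOMAIN.get(f, "other"),
                        }
                        for f in top.index
                    ],
                },
                indent=1,
            )
        )
        report.ranking = ranking  # attached for cohort summaries
        return report
    except Exception:
        if out.exists():
            shutil.rmtree(out, ignore_errors=True)
        logger.error("subject %s failed at stage %r", subject_id, stage)
        raise


def run_pipeline(config: PipelineConfig, data_dir, out_dir) -> dict:
    """Run every subject under ``data_dir``; write per-subject and cohort reports."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    subject_dirs = sorted(d for d in data_dir.iterdir() if (d / "ema.csv").exists())
    if not subject_dirs:
        raise UserError(f"no subject directories with ema.csv under {data_dir}")
    reports: dict[str, ModelReport] = {}
    for d in subject_dirs:
        rep = run_subject(config, d, out_dir)
        if rep is not None:
            reports[d.name] = rep
    if not reports:
        raise UserError("every subject was skipped; nothing to report")

    summary = cohort_statistics(reports)
    summary["per_subject"].to_csv(out_dir / "cohort_summary.csv")
    rankings = {
        sid: rep.ranking for sid, rep in reports.items() if hasattr(rep, "ranking")
    }
    payload = {k: v for k, v in summary.items() if k != "per_subject"}
    if rankings:
        payload["domain_frequencies_pct"] = domain_frequencies(rankings).to_dict()
    (out_dir / "cohort_summary.json").write_text(json.dumps(payload, indent=1))
    return {"reports": reports, "summary": summary}
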