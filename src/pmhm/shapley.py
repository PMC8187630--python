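"""Permutation Shapley attribution for fitted mood models.

A prediction is treated as a cooperative game: the features of an
instance are players, the payout is the model prediction minus the mean
prediction over a background dataset.  The value of a feature coalition
is the mean prediction with out-of-coalition features replaced by
background rows.  The permutation explainer walks sampled feature
orderings completely forward and then in reverse, toggling each feature
from its background value to the instance value and attributing the
prediction delta; each full walk telescopes exactly, so additivity
(local accuracy) holds for every explanation:

    sum_j phi_j + base_value = f(x).

One forward-reverse pass is exact for models with up to second-order
interactions (in particular, for additive models a single pass recovers
the closed form phi_j = beta_j * (x_j - mean of background x_j)); more
permutations tighten the estimate under higher-order interactions.

An exact enumeration oracle over all 2^p coalitions is provided for
testing at small p; it is exponential by design and refuses p > 12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema

__all__ = [
    "Explanation",
    "ImportanceRanking",
    "permutation_shap",
    "explain_instances",
    "exact_shap_bruteforce",
    "explain_report",
    "rank_and_summarize",
    "domain_frequencies",
]


@dataclass
class Explanation:
    """Per-feature attributions for one instance, in target units."""

    values: np.ndarray  # shape (p,)
    base_value: float
    prediction: float
    feature_names: tuple[str, ...] | None = None

    def additivity_gap(self) -> float:
        return float(abs(self.values.sum() + self.base_value - self.prediction))


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def permutation_shap(
    predict_fn,
    background,
    instance,
    n_permutations: int = 200,
    seed: int = 0,
    feature_names=None,
) -> Explanation:
    """Estimate Shapley values by forward-reverse permutation walks.

    For each sampled permutation the features are toggled from background
    to instance values in permutation order, then again in reversed
    order; each step's change in the background-averaged prediction is
    credited to the toggled feature, and credits are averaged over both
    directions and all permutations.  All coalition evaluations for one
    permutation are batched into a single ``predict_fn`` call.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    B = _as_matrix(background)
    if B.ndim != 2 or len(B) == 0:
        raise ValueError("background must be a non-empty 2-D array")
    x = np.asarray(instance, dtype=float).ravel()
    p = B.shape[1]
    if x.shape != (p,):
        raise ValueError(f"instance must have {p} features, got {x.shape}")
    nb = len(B)
    rng = np.random.default_rng(seed)

    try:
        base_value = float(np.mean(predict_fn(B)))
        prediction = float(np.mean(predict_fn(x[None, :])))
    except Exception as err:  # pragma: no cover - context for debugging
        raise RuntimeError(f"predict_fn failed on instance {x!r}") from err

    phi = np.zeros(p)
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        for order in (perm, perm[::-1]):
            # States S_0..S_p: background with the first k features (in
            # this order) set to the instance value.  Stack all p+1 states
            # and predict once.
            states = np.empty((p + 1, nb, p))
            M = B.copy()
            states[0] = M
            for k, j in enumerate(order):
                M[:, j] = x[j]
                states[k + 1] = M
            preds = predict_fn(states.reshape(-1, p)).reshape(p + 1, nb)
            means = preds.mean(axis=1)
            phi[order] += np.diff(means)
    phi /= 2 * n_permutations
    return Explanation(
        values=phi,
        base_value=base_value,
        prediction=prediction,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def explain_instances(
    predict_fn,
    background,
    instances,
    n_permutations: int = 200,
    seed: int = 0,
    feature_names=None,
) -> list[Explanation]:
    """Explain each row of ``instances``; seeds are derived per instance."""
    X = _as_matrix(instances)
    if feature_names is None and isinstance(instances, pd.DataFrame):
        feature_names = tuple(instances.columns)
    return [
        permutation_shap(
            predict_fn,
            background,
            X[i],
            n_permutations=n_permutations,
            seed=seed + i,
            feature_names=feature_names,
        )
        for i in range(len(X))
    ]


def exact_shap_bruteforce(
    predict_fn, background, instance, feature_names=None
) -> Explanation:
    """Exact Shapley values by enumerating all 2^p coalitions (p <= 12).

    Coalition value v(S) = mean prediction over background rows with the
    features in S set to the instance values; phi_j is the classically
    weighted sum of marginal contributions v(S + j) - v(S).
    """
    B = _as_matrix(background)
    x = np.asarray(instance, dtype=float).ravel()
    p = B.shape[1]
    if p > 12:
        raise ValueError(f"exact enumeration refuses p > 12 features (got {p})")
    nb = len(B)

    n_coalitions = 1 << p
    states = np.empty((n_coalitions, nb, p))
    for s_mask in range(n_coalitions):
        M = B.copy()
        for j in range(p):
            if s_mask >> j & 1:
                M[:, j] = x[j]
        states[s_mask] = M
    v = predict_fn(states.reshape(-1, p)).reshape(n_coalitions, nb).mean(axis=1)

    fact = [math.factorial(k) for k in range(p + 1)]
    phi = np.zeros(p)
    for s_mask in range(n_coalitions):
        size = bin(s_mask).count("1")
        w = fact[size] * fact[p - size - 1] / fact[p]
        for j in range(p):
            if not (s_mask >> j & 1):
                phi[j] += w * (v[s_mask | (1 << j)] - v[s_mask])
    return Explanation(
        values=phi,
        base_value=float(v[0]),
        prediction=float(v[n_coalitions - 1]),
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


# ---------------------------------------------------------------------------
# Pipeline integration: explain a subject's out-of-fold predictions.


def explain_report(
    report,
    table: pd.DataFrame,
    strategy: str | None = None,
    n_permutations: int = 200,
    background_cap: int = 100,
    max_instances: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Shapley attributions for a subject's out-of-fold instances.

    For each outer fold, the fold's fitted model explains its own test
    rows against a background of that fold's (preprocessed) training
    rows, subsampled to ``background_cap``.  Attributions therefore
    describe the predictions actually reported.  Returns a DataFrame of
    phi values (one row per explained instance, one column per feature)
    with ``base_value`` and ``prediction`` columns appended.
    """
    strategy = strategy or report.best
    X_all = table.drop(columns=[schema.TARGET])
    n = len(table)
    all_idx = np.arange(n)
    rows, index = [], []
    rng = np.random.default_rng(seed)
    for fold, te_idx in enumerate(report.fold_test_indices):
        tuned = report.fold_models[strategy][fold]
        pre = tuned.preprocessor
        tr_idx = np.setdiff1d(all_idx, te_idx)
        bg = pre.transform(X_all.iloc[tr_idx]).to_numpy()
        if len(bg) > background_cap:
            bg = bg[rng.choice(len(bg), background_cap, replace=False)]
        Xte = pre.transform(X_all.iloc[te_idx])
        te_rows = te_idx
        if max_instances is not None:
            per_fold = max(1, max_instances // len(report.fold_test_indices))
            if len(te_rows) > per_fold:
                keep = rng.choice(len(te_rows), per_fold, replace=False)
                keep.sort()
                te_rows = te_idx[keep]
                Xte = Xte.iloc[[int(np.where(te_idx == r)[0][0]) for r in te_rows]]
        explanations = explain_instances(
            tuned.estimator.predict,
            bg,
            Xte,
            n_permutations=n_permutations,
            seed=seed + 1000 * fold,
            feature_names=tuple(Xte.columns),
        )
        for ridx, expl in zip(te_rows, explanations):
            rows.append(
                np.concatenate([expl.values, [expl.base_value, expl.prediction]])
            )
            index.append(table.index[ridx])
    cols = list(X_all.columns) + ["base_value", "prediction"]
    return pd.DataFrame(rows, index=pd.Index(index, name=table.index.name), columns=cols)


# ---------------------------------------------------------------------------
# Ranking and cross-subject domain summaries.


@dataclass
class ImportanceRanking:
    """Mean |phi| per feature with ranks; top-k flags the k largest."""

    table: pd.DataFrame  # index feature; mean_abs_phi, rank, top_k
    k: int

    @property
    def top_features(self) -> list[str]:
        return list(self.table.index[self.table["top_k"]])


def rank_and_summarize(shap_values, k: int = 5) -> ImportanceRanking:
    """Rank features by mean absolute Shapley value across instances.

    ``shap_values`` is a DataFrame of per-instance phi columns (as
    returned by :func:`explain_report`; ``base_value``/``prediction``
    columns are ignored) or a list of :class:`Explanation`.
    """
    if isinstance(shap_values, pd.DataFrame):
        phi = shap_values.drop(
            columns=[c for c in ("base_value", "prediction") if c in shap_values],
        )
    else:
        if not shap_values:
            raise ValueError("no explanations to rank")
        names = shap_values[0].feature_names or tuple(
            f"f{i}" for i in range(len(shap_values[0].values))
        )
        phi = pd.DataFrame([e.values for e in shap_values], columns=list(names))
    if phi.empty:
        raise ValueError("no explanations to rank")
    mean_abs = phi.abs().mean(axis=0).sort_values(ascending=False, kind="stable")
    k_eff = min(k, len(mean_abs))
    table = pd.DataFrame(
        {
            "mean_abs_phi": mean_abs,
            "rank": np.arange(1, len(mean_abs) + 1),
            "top_k": [i < k_eff for i in range(len(mean_abs))],
        }
    )
    table.index.name = "feature"
    return ImportanceRanking(table=table, k=k)


def domain_frequencies(
    rankings: dict[str, ImportanceRanking] | list[ImportanceRanking],
    feature_domain: dict[str, str] | None = None,
) -> pd.Series:
    """Fraction of subjects (%) with >= 1 top-k feature in each domain."""
    if feature_domain is None:
        feature_domain = schema.FEATURE_DOMAIN
    items = list(rankings.values()) if isinstance(rankings, dict) else list(rankings)
    if not items:
        raise ValueError("no rankings to summarize")
    counts = {d: 0 for d in schema.DOMAINS}
    for r in items:
        domains_hit = {feature_domain.get(f, "other") for f in r.top_features}
        for d in domains_hit:
            counts[d] += 1
    return pd.Series(counts, name="pct_subjects") / len(items) * 100.0
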