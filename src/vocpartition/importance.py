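"""Permutation importance under animal-grouped cross-validation.

Within each grouped test fold, one predictor at a time is shuffled across
the held-out rows (breaking its association with the label while keeping
the joint distribution of the remaining predictors), the fold's macro-F1
is recomputed with the already-fitted fold model, and the decrement

    delta = macro-F1(baseline) - macro-F1(permuted)

is averaged over ``n_repeats`` shuffles.  Because permutation acts on the
raw feature column *before* the fold pipeline's encoding, the one-hot
dummies of a categorical predictor (sex, growth phase) are permuted
jointly as a unit — permuting dummy columns independently would create
impossible rows.  Fold-level means are aggregated as the mean with
empirical 2.5/97.5 percentiles across folds; negative importances are
reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .io_schema import CONDITION_LEVELS, FeatureTable
from .subject_cv import CVResult, _feature_columns, metrics


@dataclass
class ImportanceRecord:
    feature: str
    mean_delta_macro_f1: float
    ci_2_5: float
    ci_97_5: float
    per_fold_values: list[float]
    n_repeats: int


@dataclass
class ImportanceResult:
    records: list[ImportanceRecord]
    rank_stability_kendall_tau: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "feature": r.feature,
            "mean_delta_macro_f1": r.mean_delta_macro_f1,
            "ci_2_5": r.ci_2_5,
            "ci_97_5": r.ci_97_5,
            "n_repeats": r.n_repeats,
        } for r in self.records]
        df = pd.DataFrame(rows).sort_values("mean_delta_macro_f1",
                                            ascending=False, ignore_index=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df


def _predict_labels(pipe, df: pd.DataFrame, feat_cols: list[str]) -> np.ndarray:
    proba_raw = pipe.predict_proba(df[feat_cols])
    classes = list(pipe.named_steps["clf"].classes_)
    proba = np.zeros((len(df), len(CONDITION_LEVELS)))
    for j, c in enumerate(CONDITION_LEVELS):
        if c in classes:
            proba[:, j] = proba_raw[:, classes.index(c)]
    return np.asarray(CONDITION_LEVELS)[np.argmax(proba, axis=1)]


def permutation_importance(
    cv: CVResult,
    table: FeatureTable,
    features: Sequence[str] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceResult:
    """Grouped-fold permutation importance for a completed CV run.

    Uses the per-fold fitted pipelines and held-out rows stored on the
    :class:`CVResult`.  Returns per-feature records plus the mean pairwise
    Kendall tau between fold-wise importance rankings (ranking stability).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not cv.fold_models:
        raise ValueError("CV result carries no fitted fold models")
    num_cols, cat_cols = _feature_columns(cv.feature_spec)
    all_feats = list(num_cols) + list(cat_cols)
    if features is None:
        features = all_feats
    unknown = [f for f in features if f not in all_feats]
    if unknown:
        raise ValueError(f"feature(s) {unknown} not in the {cv.feature_spec!r} spec")

    df = table.data.reset_index(drop=True)
    if len(df) != len(cv.y_true):
        raise ValueError("table and CV result have different row counts")
    rng = np.random.default_rng(seed)

    n_folds = len(cv.fold_models)
    deltas = np.zeros((len(features), n_folds))
    for f, (pipe, test_idx) in enumerate(zip(cv.fold_models, cv.fold_test_indices)):
        test = df.loc[test_idx].reset_index(drop=True)
        y_true = test["condition"].astype(str).to_numpy()
        base = metrics(y_true, _predict_labels(pipe, test, all_feats))["macro_f1"]
        for i, feat in enumerate(features):
            reps = np.empty(n_repeats)
            for r in range(n_repeats):
                shuffled = test.copy()
                shuffled[feat] = shuffled[feat].to_numpy()[
                    rng.permutation(len(shuffled))]
                perm_f1 = metrics(
                    y_true, _predict_labels(pipe, shuffled, all_feats))["macro_f1"]
                reps[r] = base - perm_f1
            deltas[i, f] = reps.mean()

    records = []
    for i, feat in enumerate(features):
        vals = deltas[i]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        records.append(ImportanceRecord(
            feature=feat, mean_delta_macro_f1=float(vals.mean()),
            ci_2_5=float(lo), ci_97_5=float(hi),
            per_fold_values=[float(v) for v in vals], n_repeats=n_repeats))

    stability = None
    if n_folds >= 2 and len(features) >= 2:
        taus = []
        for a in range(n_folds):
            for b in range(a + 1, n_folds):
                tau, _ = kendalltau(deltas[:, a], deltas[:, b])
                if np.isfinite(tau):
                    taus.append(tau)
        stability = float(np.mean(taus)) if taus else None
    return ImportanceResult(records=records, rank_stability_kendall_tau=stability)
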