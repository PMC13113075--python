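"""Subject-wise (animal-grouped) cross-validated distress classification.

The hard constraint is identity-leakage prevention: every fold assigns all
samples of an animal to either training or test, never both, so metrics
estimate generalization to unseen individuals.  All preprocessing
(median/mode imputation, z-scaling for the linear model) is fitted on the
training fold only and applied to the held-out fold — a leakage-free
pipeline, enforced by construction via sklearn Pipelines.

Three classifiers ship with fixed, documented defaults: an L2-regularized
multinomial logistic regression (C=1, balanced class weights), a
500-tree random forest, and a histogram gradient-boosting ensemble.
Metrics follow the multi-class conventions: balanced accuracy is the
unweighted mean of per-class recalls and macro-F1 the unweighted mean of
per-class F1 scores.

``run_recordwise_cv`` deliberately ignores the grouping constraint
(stratified sample-level folds).  It exists to *demonstrate* the
identity-leakage inflation that grouped CV prevents, not as an evaluation
protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .io_schema import CONDITION_LEVELS, TRAITS, FeatureTable

#: Feature specifications: numeric acoustic traits plus optional factor
#: covariates.  "acoustics" is the metadata-free sensitivity variant,
#: "nopitch" the pitch-missingness sensitivity variant.
FEATURE_SPECS: dict[str, dict[str, tuple[str, ...]]] = {
    "full": {"numeric": TRAITS, "categorical": ("sex", "phase")},
    "acoustics": {"numeric": TRAITS, "categorical": ()},
    "nopitch": {"numeric": tuple(t for t in TRAITS if t != "pitch"),
                "categorical": ("sex", "phase")},
}

MODEL_NAMES = ("logit", "rf", "gbm")


class LeakageError(RuntimeError):
    """An animal appears in both the training and the test set."""


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of animals to cross-validation folds."""

    k: int
    assignments: dict[str, int]
    seed: int
    stratified: bool = True

    def animals_in_fold(self, fold: int) -> list[str]:
        return sorted(a for a, f in self.assignments.items() if f == fold)

    def validate(self) -> None:
        folds = set(self.assignments.values())
        if folds != set(range(self.k)):
            raise ValueError("every fold index in 0..k-1 must be non-empty")


@dataclass
class CVResult:
    model_name: str
    feature_spec: str
    plan: FoldPlan | None
    indices: np.ndarray                 # row positions of pooled predictions
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: pd.DataFrame                 # columns = CONDITION_LEVELS
    fold_of_row: np.ndarray
    per_fold: pd.DataFrame              # fold, n_test, balanced_accuracy, macro_f1
    balanced_accuracy: float
    macro_f1: float
    per_class: pd.DataFrame             # precision, recall, f1, support
    confusion_raw: pd.DataFrame
    confusion_row_norm: pd.DataFrame
    fold_models: list = field(default_factory=list, repr=False)
    fold_test_indices: list = field(default_factory=list, repr=False)


# ---- fold construction -------------------------------------------------


def make_grouped_folds(
    table: FeatureTable,
    k: int = 5,
    seed: int = 0,
    stratify_by: str | None = "condition",
) -> FoldPlan:
    """Partition animals into k folds, balancing class counts greedily.

    Fold sizes (in animals) differ by at most one.  With ``stratify_by``
    set, animals are assigned largest-first to the fold that keeps
    per-fold class counts closest to the global proportions, subject to
    the capacity constraint; with ``stratify_by=None`` the split is a
    seeded random chunking.  Deterministic under ``seed``.
    """
    df = table.data
    animals = sorted(df["animal_id"].unique())
    if k > len(animals):
        raise ValueError(f"k={k} exceeds the number of animals ({len(animals)})")
    rng = np.random.default_rng(seed)

    if stratify_by is None:
        order = rng.permutation(len(animals))
        assignments = {animals[i]: int(j * k // len(animals))
                       for j, i in enumerate(order)}
        return FoldPlan(k=k, assignments=assignments, seed=seed, stratified=False)

    classes = sorted(df[stratify_by].dropna().unique())
    counts = (df.groupby(["animal_id", stratify_by], observed=True).size()
              .unstack(fill_value=0).reindex(index=animals, columns=classes,
                                             fill_value=0))
    target = counts.sum(axis=0).to_numpy() / k
    cap = int(np.ceil(len(animals) / k))

    # largest animals first; seeded shuffle breaks ties deterministically
    perm = rng.permutation(len(animals))
    order = sorted(perm, key=lambda i: (-counts.iloc[i].sum(), i))
    fold_counts = np.zeros((k, len(classes)))
    fold_sizes = np.zeros(k, dtype=int)
    assignments: dict[str, int] = {}
    for i in order:
        a = animals[i]
        c = counts.iloc[i].to_numpy()
        best, best_cost = None, np.inf
        for f in range(k):
            if fold_sizes[f] >= cap:
                continue
            cost = float(((fold_counts[f] + c - target) ** 2).sum())
            if cost < best_cost:
                best, best_cost = f, cost
        assignments[a] = best
        fold_counts[best] += c
        fold_sizes[best] += 1
    plan = FoldPlan(k=k, assignments=assignments, seed=seed, stratified=True)
    plan.validate()
    return plan


# ---- per-fold fitting --------------------------------------------------


def _make_estimator(model: str, seed: int, params: Mapping | None = None):
    params = dict(params or {})
    if model == "logit":
        defaults = dict(C=1.0, class_weight="balanced", max_iter=5000)
        defaults.update(params)
        return LogisticRegression(**defaults), True
    if model == "rf":
        defaults = dict(n_estimators=500, random_state=seed, n_jobs=1)
        defaults.update(params)
        return RandomForestClassifier(**defaults), False
    if model == "gbm":
        defaults = dict(random_state=seed)
        defaults.update(params)
        return HistGradientBoostingClassifier(**defaults), False
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def _feature_columns(feature_spec: str) -> tuple[list[str], list[str]]:
    if feature_spec not in FEATURE_SPECS:
        raise ValueError(f"unknown feature spec {feature_spec!r}; "
                         f"choose from {list(FEATURE_SPECS)}")
    spec = FEATURE_SPECS[feature_spec]
    return list(spec["numeric"]), list(spec["categorical"])


def fit_fold(
    train: pd.DataFrame,
    test: pd.DataFrame,
    model: str = "rf",
    feature_spec: str = "full",
    seed: int = 0,
    model_params: Mapping | None = None,
    _check_groups: bool = True,
) -> tuple[np.ndarray, np.ndarray, Pipeline]:
    """Fit one fold and predict the held-out rows.

    Imputation statistics (train-fold median / most-frequent) and the
    z-scaler for the linear model are fitted on the training rows only.
    Constant training features are dropped with a warning.  Probability
    columns follow the canonical condition order and the predicted label is
    its argmax, so ties break by the fixed class order.
    """
    if _check_groups:
        shared = set(train["animal_id"]) & set(test["animal_id"])
        if shared:
            raise LeakageError(f"animals in both train and test: {sorted(shared)[:5]}")
    num_cols, cat_cols = _feature_columns(feature_spec)

    train_classes = set(train["condition"].unique())
    missing_classes = set(test["condition"].unique()) - train_classes
    if missing_classes:
        raise ValueError(
            f"class(es) {sorted(missing_classes)} absent from the training fold; "
            "use a stratified fold plan")

    constant = [c for c in num_cols
                if train[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"dropping zero-variance training feature(s): {constant}",
                      UserWarning, stacklevel=2)
        num_cols = [c for c in num_cols if c not in constant]

    estimator, scale = _make_estimator(model, seed, model_params)
    num_steps = [("impute", SimpleImputer(strategy="median"))]
    if scale:
        num_steps.append(("scale", StandardScaler()))
    transformers = [("num", Pipeline(num_steps), num_cols)]
    if cat_cols:
        transformers.append((
            "cat",
            Pipeline([("impute", SimpleImputer(strategy="most_frequent")),
                      ("onehot", OneHotEncoder(handle_unknown="ignore"))]),
            cat_cols,
        ))
    pipe = Pipeline([
        ("prep", ColumnTransformer(transformers, remainder="drop")),
        ("clf", estimator),
    ])
    feat_cols = num_cols + cat_cols
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        pipe.fit(train[feat_cols], train["condition"].astype(str))
        proba_raw = pipe.predict_proba(test[feat_cols])
    # reorder probability columns to the canonical class order
    classes = list(pipe.named_steps["clf"].classes_)
    proba = np.zeros((len(test), len(CONDITION_LEVELS)))
    for j, c in enumerate(CONDITION_LEVELS):
        if c in classes:
            proba[:, j] = proba_raw[:, classes.index(c)]
    pred = np.asarray(CONDITION_LEVELS)[np.argmax(proba, axis=1)]
    return pred, proba, pipe


# ---- metrics -----------------------------------------------------------


def metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    labels: Sequence[str] = CONDITION_LEVELS,
) -> dict:
    """Balanced accuracy, macro-F1 and per-class precision/recall/F1.

    Balanced accuracy averages recalls over classes with support > 0;
    macro-F1 averages F1 over the same classes; F1 := 0 when P + R = 0.
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    extra = (set(y_true) | set(y_pred)) - set(labels)
    if extra:
        raise ValueError(f"labels outside the class set: {sorted(extra)}")
    K = len(labels)
    cm = np.zeros((K, K), dtype=int)
    index = {c: i for i, c in enumerate(labels)}
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    support = cm.sum(axis=1)
    pred_n = cm.sum(axis=0)
    diag = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, diag / np.maximum(support, 1), np.nan)
        precision = np.where(pred_n > 0, diag / np.maximum(pred_n, 1), 0.0)
        pr = precision + recall
        f1 = np.where(np.nan_to_num(pr) > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    present = support > 0
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": support},
        index=list(labels))
    cm_df = pd.DataFrame(cm, index=list(labels), columns=list(labels))
    row_norm = cm_df.div(np.maximum(support, 1), axis=0)
    return {
        "balanced_accuracy": float(np.nanmean(recall[present])),
        "macro_f1": float(np.mean(f1[present])),
        "per_class": per_class,
        "confusion_raw": cm_df,
        "confusion_row_norm": row_norm,
    }


# ---- cross-validation drivers ------------------------------------------


def _pool_and_score(model: str, feature_spec: str, plan: FoldPlan | None,
                    df: pd.DataFrame, fold_rows: list[np.ndarray],
                    seed: int, model_params: Mapping | None,
                    check_groups: bool) -> CVResult:
    n = len(df)
    y_pred = np.empty(n, dtype=object)
    proba = np.zeros((n, len(CONDITION_LEVELS)))
    fold_of_row = np.full(n, -1, dtype=int)
    per_fold_rows, fold_models, fold_test_indices = [], [], []
    for f, test_idx in enumerate(fold_rows):
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        train, test = df.loc[~mask], df.loc[mask]
        pred, pr, pipe = fit_fold(train, test, model=model,
                                  feature_spec=feature_spec, seed=seed,
                                  model_params=model_params,
                                  _check_groups=check_groups)
        y_pred[test_idx] = pred
        proba[test_idx] = pr
        fold_of_row[test_idx] = f
        m = metrics(test["condition"].astype(str), pred)
        per_fold_rows.append({"fold": f, "n_test": len(test),
                              "balanced_accuracy": m["balanced_accuracy"],
                              "macro_f1": m["macro_f1"]})
        fold_models.append(pipe)
        fold_test_indices.append(test_idx)
    assert (fold_of_row >= 0).all(), "every sample must be predicted exactly once"
    y_true = df["condition"].astype(str).to_numpy()
    pooled = metrics(y_true, y_pred)
    return CVResult(
        model_name=model, feature_spec=feature_spec, plan=plan,
        indices=np.arange(n), y_true=y_true, y_pred=y_pred.astype(str),
        proba=pd.DataFrame(proba, columns=list(CONDITION_LEVELS)),
        fold_of_row=fold_of_row,
        per_fold=pd.DataFrame(per_fold_rows),
        balanced_accuracy=pooled["balanced_accuracy"],
        macro_f1=pooled["macro_f1"],
        per_class=pooled["per_class"],
        confusion_raw=pooled["confusion_raw"],
        confusion_row_norm=pooled["confusion_row_norm"],
        fold_models=fold_models, fold_test_indices=fold_test_indices,
    )


def run_cv(
    table: FeatureTable,
    plan: FoldPlan,
    models: Sequence[str] = ("logit", "rf", "gbm"),
    feature_spec: str = "full",
    missing: str = "impute",
    seed: int = 0,
    model_params: Mapping[str, Mapping] | None = None,
) -> dict[str, CVResult]:
    """Animal-grouped cross-validation for one or more classifiers.

    ``missing="impute"`` keeps pitch-missing rows (train-fold median);
    ``missing="complete-case"`` restricts the analysis to observed-pitch
    rows before folding.
    """
    if missing not in ("impute", "complete-case"):
        raise ValueError(f"unknown missing-data strategy {missing!r}")
    df = table.data.reset_index(drop=True)
    if missing == "complete-case" and "pitch" in df.columns:
        df = df[df["pitch"].notna()].reset_index(drop=True)
    plan.validate()
    fold_rows = []
    for f in range(plan.k):
        animals = set(plan.animals_in_fold(f))
        fold_rows.append(np.flatnonzero(df["animal_id"].isin(animals)))
    out = {}
    for model in models:
        mp = (model_params or {}).get(model)
        out[model] = _pool_and_score(model, feature_spec, plan, df, fold_rows,
                                     seed, mp, check_groups=True)
    return out


def run_recordwise_cv(
    table: FeatureTable,
    k: int = 5,
    models: Sequence[str] = ("rf",),
    feature_spec: str = "full",
    seed: int = 0,
    model_params: Mapping[str, Mapping] | None = None,
) -> dict[str, CVResult]:
    """Sample-level stratified CV that IGNORES animal grouping.

    The identity-leakage comparator: samples from the same animal (and the
    same 60 s recording) land in both training and test, so stable vocal
    signatures inflate apparent performance.
    """
    df = table.data.reset_index(drop=True)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_rows = [test for _, test in skf.split(df, df["condition"].astype(str))]
    out = {}
    for model in models:
        mp = (model_params or {}).get(model)
        out[model] = _pool_and_score(model, feature_spec, None, df, fold_rows,
                                     seed, mp, check_groups=False)
    return out
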