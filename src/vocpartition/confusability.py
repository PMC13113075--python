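"""Confusability / overlap structure of distress classes.

From pooled out-of-fold predictions this module derives:

* the row-normalized (directional) confusion matrix C(a->b) = P(pred b | true a);
* the symmetric confusability index S(a,b) = [C(a->b) + C(b->a)] / 2, an
  undirected overlap measure robust to class imbalance;
* per-sample uncertainty: Shannon entropy of the predicted class
  probabilities (natural log; maximum ln K) and the margin between the top
  two probabilities;
* phase-stratified recomputation of all of the above;
* average-linkage hierarchical clustering of classes on distance 1 - S,
  with the cluster count chosen at the largest merge-height gap and
  fold-to-fold stability scored by the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from .io_schema import CONDITION_LEVELS, FeatureTable
from .subject_cv import CVResult
from .variance_partition import bh_fdr


# ---- matrices ----------------------------------------------------------


def directional_confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    labels: Sequence[str] = CONDITION_LEVELS,
) -> pd.DataFrame:
    """Row-normalized confusion matrix C(a->b); unsupported rows are NaN."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    K = len(labels)
    counts = np.zeros((K, K))
    idx = {c: i for i, c in enumerate(labels)}
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    support = counts.sum(axis=1)
    C = np.full((K, K), np.nan)
    rows = support > 0
    C[rows] = counts[rows] / support[rows, None]
    return pd.DataFrame(C, index=list(labels), columns=list(labels))


def symmetric_index(C: pd.DataFrame) -> pd.DataFrame:
    """S(a,b) = [C(a->b) + C(b->a)] / 2; the diagonal is left undefined."""
    if C.shape[0] != C.shape[1]:
        raise ValueError("directional matrix must be square")
    S = (C.to_numpy() + C.to_numpy().T) / 2.0
    np.fill_diagonal(S, np.nan)
    return pd.DataFrame(S, index=C.index, columns=C.columns)


# ---- per-sample uncertainty --------------------------------------------


def _check_proba(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probability vectors must sum to 1 within 1e-6")
    if np.any(p < -1e-12):
        raise ValueError("negative probabilities")
    return np.clip(p, 0.0, 1.0)


def prediction_entropy(p: np.ndarray) -> np.ndarray | float:
    """Shannon entropy -sum p log p (natural log, 0 log 0 := 0)."""
    arr = _check_proba(np.atleast_2d(p))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0, arr * np.log(arr), 0.0)
    h = np.maximum(-terms.sum(axis=1), 0.0)   # avoid -0.0 on one-hot input
    return float(h[0]) if np.ndim(p) == 1 else h


def prediction_margin(p: np.ndarray) -> np.ndarray | float:
    """Top minus second-highest predicted probability."""
    arr = _check_proba(np.atleast_2d(p))
    if arr.shape[1] < 2:
        raise ValueError("margin needs at least 2 classes")
    part = np.sort(arr, axis=1)
    m = part[:, -1] - part[:, -2]
    return float(m[0]) if np.ndim(p) == 1 else m


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return np.nan, np.nan
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)


# ---- summaries ---------------------------------------------------------


@dataclass
class ClusterResult:
    labels: dict[str, int]
    n_clusters: int
    cut_height: float
    stability: float | None            # mean ARI of per-fold vs pooled clustering
    notice: str | None = None


@dataclass
class OverlapSummary:
    classes: tuple[str, ...]
    directional: pd.DataFrame
    symmetric: pd.DataFrame
    entropy_by_class: pd.DataFrame     # median, iqr, n per class
    margin_by_class: pd.DataFrame
    strata: dict[str, "OverlapSummary"] = field(default_factory=dict)
    clusters: ClusterResult | None = None
    skipped_strata: dict[str, str] = field(default_factory=dict)


def _uncertainty_tables(y_true: np.ndarray, proba: np.ndarray,
                        labels: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    H = prediction_entropy(proba)
    M = prediction_margin(proba)
    ent_rows, mar_rows = [], []
    for c in labels:
        mask = y_true == c
        med, iqr = _median_iqr(H[mask])
        ent_rows.append({"class": c, "median": med, "iqr": iqr, "n": int(mask.sum())})
        med, iqr = _median_iqr(M[mask])
        mar_rows.append({"class": c, "median": med, "iqr": iqr, "n": int(mask.sum())})
    return (pd.DataFrame(ent_rows).set_index("class"),
            pd.DataFrame(mar_rows).set_index("class"))


def overlap_summary(
    cv: CVResult,
    table: FeatureTable | None = None,
    stratify: str | None = "phase",
    with_clusters: bool = True,
) -> OverlapSummary:
    """Full overlap analysis of one model's pooled out-of-fold predictions."""
    labels = tuple(CONDITION_LEVELS)
    C = directional_confusion(cv.y_true, cv.y_pred, labels)
    S = symmetric_index(C)
    proba = cv.proba.to_numpy()
    ent, mar = _uncertainty_tables(cv.y_true, proba, labels)
    summary = OverlapSummary(classes=labels, directional=C, symmetric=S,
                             entropy_by_class=ent, margin_by_class=mar)
    if stratify is not None and table is not None:
        summary.strata, summary.skipped_strata = stratified_overlap(cv, table, stratify)
    if with_clusters:
        fold_S = []
        for f in sorted(set(cv.fold_of_row)):
            m = cv.fold_of_row == f
            Cf = directional_confusion(cv.y_true[m], cv.y_pred[m], labels)
            fold_S.append(symmetric_index(Cf))
        summary.clusters = cluster_overlap(S, fold_S)
    return summary


def stratified_overlap(
    cv: CVResult,
    table: FeatureTable,
    stratum: str = "phase",
) -> tuple[dict[str, OverlapSummary], dict[str, str]]:
    """Recompute the overlap maps within each level of ``stratum``.

    Strata in which fewer than two classes are represented are skipped with
    a notice rather than computed.
    """
    df = table.data.reset_index(drop=True)
    if len(df) != len(cv.y_true):
        raise ValueError("table and CV result have different row counts "
                         "(was the CV run complete-case?)")
    values = df[stratum].astype(str).to_numpy()
    out: dict[str, OverlapSummary] = {}
    skipped: dict[str, str] = {}
    for level in pd.unique(values):
        mask = values == level
        present = set(cv.y_true[mask])
        if len(present) < 2:
            skipped[level] = f"only {len(present)} class(es) represented"
            continue
        C = directional_confusion(cv.y_true[mask], cv.y_pred[mask], CONDITION_LEVELS)
        S = symmetric_index(C)
        ent, mar = _uncertainty_tables(cv.y_true[mask], cv.proba.to_numpy()[mask],
                                       CONDITION_LEVELS)
        out[level] = OverlapSummary(classes=tuple(CONDITION_LEVELS), directional=C,
                                    symmetric=S, entropy_by_class=ent,
                                    margin_by_class=mar)
    return out, skipped


# ---- clustering --------------------------------------------------------


def _cluster_once(S: pd.DataFrame) -> tuple[dict[str, int], int, float]:
    D = 1.0 - np.nan_to_num(S.to_numpy(), nan=0.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = np.concatenate([[0.0], Z[:, 2]])
    gaps = np.diff(heights)
    cut = (heights[np.argmax(gaps)] + heights[np.argmax(gaps) + 1]) / 2.0
    labels = fcluster(Z, t=cut, criterion="distance")
    return dict(zip(S.index, (int(x) for x in labels))), int(labels.max()), float(cut)


def cluster_overlap(
    S: pd.DataFrame,
    fold_S: Sequence[pd.DataFrame] | None = None,
) -> ClusterResult:
    """Average-linkage clustering of classes on distance 1 - S.

    The cluster count is chosen by the largest gap in the merge-height
    sequence (cut midway through the gap, with height 0 prepended so that a
    flat dendrogram yields all singletons).  Stability is the mean adjusted
    Rand index between each per-fold clustering and the pooled one.
    """
    if S.shape[0] < 3:
        return ClusterResult(labels={}, n_clusters=0, cut_height=np.nan,
                             stability=None, notice="K < 3; clustering skipped")
    labels, n_clusters, cut = _cluster_once(S)
    stability = None
    if fold_S:
        pooled = [labels[c] for c in S.index]
        aris = []
        for Sf in fold_S:
            lf, _, _ = _cluster_once(Sf)
            aris.append(adjusted_rand_score(pooled, [lf[c] for c in S.index]))
        stability = float(np.mean(aris))
    return ClusterResult(labels=labels, n_clusters=n_clusters,
                         cut_height=cut, stability=stability)


# ---- class comparisons -------------------------------------------------


def compare_uncertainty_by_class(
    y_true: np.ndarray,
    values: np.ndarray,
    labels: Sequence[str] = CONDITION_LEVELS,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests of a per-sample uncertainty measure
    between classes, BH-adjusted across all pairs."""
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va = values[y_true == a]
            vb = values[y_true == b]
            if len(va) == 0 or len(vb) == 0:
                continue
            stat, p = mannwhitneyu(va, vb, alternative="two-sided")
            rows.append({"class_a": a, "class_b": b, "u": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out
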