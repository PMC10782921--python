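"""Evaluation machinery: confusion-derived point metrics, ROC/PR areas,
repeated stratified cross-validation, the two-set Davies-Bouldin separation
index, motif enrichment scores, aggregate peak analysis and branch ablation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .model import GraphData

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_metrics",
    "auroc",
    "aupr",
    "repeated_cv",
    "davies_bouldin",
    "motif_enrichment_scores",
    "apa_scores",
    "ablate",
    "welch_ttest",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Point metrics from a confusion table.

    Acc = (TP+TN)/N, Sen = TP/(TP+FN), Spe = TN/(TN+FP), PPV = TP/(TP+FP),
    F1 = 2*PPV*Sen/(PPV+Sen), MCC = (TP*TN - FN*FP)/sqrt of the product of
    the four marginals.  Zero-denominator ratios are reported as NaN with a
    warning, never silently as 0.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    acc = (tp + tn) / counts.total
    sen = _ratio(tp, tp + fn, "Sen")
    spe = _ratio(tn, tn + fp, "Spe")
    ppv = _ratio(tp, tp + fp, "PPV")
    if np.isnan(ppv) or np.isnan(sen) or (ppv + sen) == 0:
        warnings.warn("F1 undefined; reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * ppv * sen / (ppv + sen)
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fn * fp, denom, "MCC")
    return {"Acc": acc, "Sen": sen, "Spe": spe, "PPV": ppv, "F1": f1, "MCC": mcc}


def auroc(y_true, scores) -> float:
    """Area under the ROC curve by the rank statistic, ties split evenly."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    return float(
        (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def aupr(y_true, scores) -> float:
    """Area under the precision-recall curve by trapezoidal integration over
    distinct score thresholds (descending)."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    if n_pos == 0:
        raise ValueError("AUPR requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # threshold boundaries: last index of each distinct score
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    cut = np.r_[distinct, len(s) - 1]
    precision = tp[cut] / (tp[cut] + fp[cut])
    recall = tp[cut] / n_pos
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    return float(np.trapezoid(precision, recall))


@dataclass
class MetricsReport:
    """Per-repetition metric values and their mean / sample-SD summary."""

    per_repetition: pd.DataFrame
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        mean = self.per_repetition.mean()
        sd = self.per_repetition.std(ddof=1)
        self.summary = pd.DataFrame({"mean": mean, "sd": sd})

    def __getitem__(self, metric: str) -> tuple[float, float]:
        return (
            float(self.summary.loc[metric, "mean"]),
            float(self.summary.loc[metric, "sd"]),
        )


def _score_fold(estimator, X, y, train_idx, test_idx, test_isolation, threshold):
    y_masked = y.copy()
    y_masked[test_idx] = -1
    est = clone(estimator)
    if test_isolation:
        keep = np.setdiff1d(np.arange(X.n_nodes), test_idx)
        sub = X.subset(keep)
        est.fit(sub, y_masked[keep])
        scores = est.predict_proba(X, indices=test_idx)[:, 1]
    else:
        est.fit(X, y_masked)
        scores = est.predict_proba(X, indices=test_idx)[:, 1]
    y_test = y[test_idx]
    preds = (scores >= threshold).astype(int)
    out = confusion_metrics(ConfusionCounts.from_predictions(y_test, preds))
    out["AUROC"] = auroc(y_test, scores)
    out["AUPR"] = aupr(y_test, scores)
    return out


def repeated_cv(
    estimator,
    X: GraphData,
    y,
    k: int = 5,
    reps: int = 5,
    seed: int = 0,
    level: str = "rep",
    test_isolation: bool = False,
    threshold: float = 0.5,
) -> MetricsReport:
    """Repeated stratified k-fold cross-validation over the labelled nodes.

    Each repetition draws a fresh stratified partition (seeded).  By default
    the estimator trains on the full graph with test-node labels masked to
    ``-1``; ``test_isolation=True`` instead removes test nodes from the graph
    during training, so their features cannot reach the aggregation.
    ``level`` controls whether rows of the report are repetition means
    (``"rep"``, the default used for summary SDs) or individual folds
    (``"fold"``).
    """
    y = np.asarray(y, dtype=np.int64)
    labeled = np.flatnonzero(y >= 0)
    if np.unique(y[labeled]).size < 2:
        raise ValueError("cross-validation requires both classes")
    if k < 2:
        raise ValueError("k must be >= 2")
    rows = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        fold_rows = []
        for train_l, test_l in skf.split(labeled, y[labeled]):
            fold_rows.append(
                _score_fold(
                    estimator, X, y, labeled[train_l], labeled[test_l],
                    test_isolation, threshold,
                )
            )
        if level == "fold":
            rows.extend(fold_rows)
        else:
            rows.append(pd.DataFrame(fold_rows).mean().to_dict())
    return MetricsReport(pd.DataFrame(rows))


def davies_bouldin(positive_vectors, negative_vectors) -> float:
    """Two-set separation index: (v(T+) + v(T-)) / |m(T+) - m(T-)|^2.

    ``m`` is the centroid and ``v`` the mean squared Euclidean deviation from
    it (population form, dividing by n).  Smaller means better separated.
    Identical centroids raise (zero denominator).
    """
    pos = np.atleast_2d(np.asarray(positive_vectors, dtype=np.float64))
    neg = np.atleast_2d(np.asarray(negative_vectors, dtype=np.float64))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both sets must be non-empty")
    if pos.shape[1] != neg.shape[1]:
        raise ValueError("sets must share the vector dimension")
    m_pos, m_neg = pos.mean(axis=0), neg.mean(axis=0)
    v_pos = float(np.mean(np.sum((pos - m_pos) ** 2, axis=1)))
    v_neg = float(np.mean(np.sum((neg - m_neg) ** 2, axis=1)))
    dist2 = float(np.sum((m_pos - m_neg) ** 2))
    if dist2 == 0:
        raise ValueError("identical set centers: separation index undefined")
    return (v_pos + v_neg) / dist2


def motif_enrichment_scores(
    match_counts: Mapping[str, float] | Sequence[float],
) -> dict:
    """Per-motif enrichment e_k = -ln(c_k / sum_j c_j).

    Motifs with zero matches have an infinite score and are omitted with a
    warning.
    """
    if isinstance(match_counts, Mapping):
        items = list(match_counts.items())
    else:
        items = list(enumerate(match_counts))
    counts = np.array([c for _, c in items], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("match counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total match count must be positive")
    out = {}
    for (key, c) in items:
        if c == 0:
            warnings.warn(
                f"motif {key!r} has zero matches (infinite score); omitted",
                stacklevel=2,
            )
            continue
        out[key] = float(-np.log(c / total))
    return out


def apa_scores(
    window_stack, corner_size: int | None = None
) -> tuple[float, float]:
    """Aggregate peak analysis scores of a stack of contact submatrices.

    The stack is aggregated by element-wise mean; on the aggregate window W
    of odd side s, with c x c lower-left corner block (default
    ``c = max(3, s // 4)``):

    * P2LL  = W[center] / mean(corner)
    * ZscoreLL = (W[center] - mean(corner)) / population-sd(corner)
    """
    stack = np.asarray(window_stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("expected a stack of square matrices")
    side = stack.shape[1]
    if side % 2 == 0:
        raise ValueError("window side must be odd (defined central pixel)")
    c = corner_size if corner_size is not None else max(3, side // 4)
    if c >= (side + 1) // 2:
        raise ValueError(f"corner size {c} must be < side/2 = {side / 2}")
    W = stack.mean(axis=0)
    center = W[side // 2, side // 2]
    corner = W[-c:, :c]
    mu = float(corner.mean())
    sd = float(corner.std())  # population sd
    if mu == 0:
        raise ValueError("zero corner mean: P2LL undefined")
    p2ll = float(center / mu)
    if sd == 0:
        raise ValueError("zero corner sd: ZscoreLL undefined")
    zscore = float((center - mu) / sd)
    return p2ll, zscore


def ablate(X: GraphData, mode: str) -> GraphData:
    """Return a view of the inputs with one branch's information removed.

    ``full`` leaves inputs unchanged; ``linear_only`` zeroes the descriptors
    and removes all edges (the graph branch sees nothing); ``topology_only``
    zeroes the linear features (the CNN sees nothing).
    """
    if mode == "full":
        return GraphData(X.linear, X.descriptors, X.edges)
    if mode == "linear_only":
        return GraphData(
            X.linear,
            np.zeros_like(X.descriptors),
            np.empty((0, 2), dtype=np.int64),
        )
    if mode == "topology_only":
        if X.linear is None:
            raise ValueError("no linear features to zero")
        return GraphData(np.zeros_like(X.linear), X.descriptors, X.edges)
    raise ValueError(
        f"unknown ablation mode {mode!r}; expected full, linear_only or topology_only"
    )


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-tailed Welch t-test between per-repetition metric samples."""
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
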