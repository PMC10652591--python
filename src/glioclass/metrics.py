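"""Multiclass performance metrics from confusion matrices.

The evaluation suite used throughout the package: accuracy, sensitivity
(recall), specificity, precision, F1, false-positive rate, geometric mean of
per-class sensitivities, and the Matthews correlation coefficient, plus
aggregation of per-fold records into means with t-based 95% confidence
intervals.

All multiclass rate metrics are macro-averaged over one-vs-rest reductions of
the confusion matrix; the MCC uses the multiclass generalization
(Gorodkin), which reduces exactly to the familiar binary formula
(TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) when K = 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

METRIC_NAMES = [
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "fpr",
    "gmean",
    "mcc",
]

#: valid range per metric, used to clip confidence intervals
METRIC_RANGES = {name: (0.0, 1.0) for name in METRIC_NAMES}
METRIC_RANGES["mcc"] = (-1.0, 1.0)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K confusion matrix; rows are true classes, columns predicted."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix dimension")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsSummary:
    """Per-fold metric records with per-metric mean and confidence interval."""

    folds: pd.DataFrame  # one row per fold, columns = METRIC_NAMES
    mean: pd.Series
    ci_lo: pd.Series
    ci_hi: pd.Series
    ci_level: float = 0.95


def confusion_matrix(y_true: Sequence, y_pred: Sequence, labels: Sequence | None = None) -> ConfusionMatrix:
    """Count (true, predicted) label co-occurrences.

    ``labels`` fixes class order; defaults to the sorted union of observed
    labels. Labels outside the declared set raise.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted labels"
        )
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    unknown = (set(y_true) | set(y_pred)) - set(labels)
    if unknown:
        raise ValueError(f"labels not in declared set: {sorted(unknown)}")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(labels), counts)


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    """Elementwise num/den with the 0-on-zero-denominator convention."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    if not ok.all():
        warnings.warn(
            f"{what}: zero denominator for {int((~ok).sum())} class(es); "
            "contributing 0 to the macro average",
            RuntimeWarning,
            stacklevel=3,
        )
    out[ok] = num[ok] / den[ok]
    return out


def compute_metrics(cm: ConfusionMatrix, averaging: str = "macro") -> dict:
    """Compute the eight-metric record from a confusion matrix.

    Per-class TP/FP/TN/FN come from one-vs-rest reduction; rate metrics are
    macro-averaged; gmean is the K-th root of the product of per-class
    sensitivities; MCC is the multiclass correlation coefficient.
    """
    if averaging != "macro":
        raise ValueError(f"unsupported averaging scheme: {averaging!r}")
    C = cm.counts.astype(float)
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(C)
    fn = C.sum(axis=1) - tp
    fp = C.sum(axis=0) - tp
    tn = n - tp - fn - fp

    recall = _safe_ratio(tp, tp + fn, "sensitivity")
    specificity = _safe_ratio(tn, tn + fp, "specificity")
    precision = _safe_ratio(tp, tp + fp, "precision")
    f1 = _safe_ratio(2 * tp, 2 * tp + fp + fn, "f1")
    fpr = _safe_ratio(fp, tn + fp, "fpr")

    # Multiclass MCC (reduces to the binary TP/TN/FP/FN formula at K = 2)
    t_k = C.sum(axis=1)  # true occurrences per class
    p_k = C.sum(axis=0)  # predicted occurrences per class
    c = tp.sum()
    cov_ytyp = c * n - t_k @ p_k
    cov_ypyp = n * n - p_k @ p_k
    cov_ytyt = n * n - t_k @ t_k
    denom = np.sqrt(cov_ypyp) * np.sqrt(cov_ytyt)
    mcc = 0.0 if denom == 0 else float(cov_ytyp / denom)

    k = len(cm.labels)
    gmean = float(np.prod(recall) ** (1.0 / k))

    return {
        "accuracy": float(c / n),
        "sensitivity": float(recall.mean()),
        "specificity": float(specificity.mean()),
        "precision": float(precision.mean()),
        "f1": float(f1.mean()),
        "fpr": float(fpr.mean()),
        "gmean": gmean,
        "mcc": mcc,
    }


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest TP/FP/TN/FN and rate metrics per class (no averaging).

    For a binary matrix, each class's row evaluates the classic two-class
    formulas with that class taken as positive.
    """
    C = cm.counts.astype(float)
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(C)
    fn = C.sum(axis=1) - tp
    fp = C.sum(axis=0) - tp
    tn = n - tp - fn - fp
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pd.DataFrame(
            {
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "sensitivity": _safe_ratio(tp, tp + fn, "sensitivity"),
                "specificity": _safe_ratio(tn, tn + fp, "specificity"),
                "precision": _safe_ratio(tp, tp + fp, "precision"),
                "f1": _safe_ratio(2 * tp, 2 * tp + fp + fn, "f1"),
                "fpr": _safe_ratio(fp, tn + fp, "fpr"),
            },
            index=list(cm.labels),
        )
    num = tp * tn - fp * fn
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    table["mcc"] = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return table


def summarize_folds(records: list[dict], ci_level: float = 0.95) -> MetricsSummary:
    """Aggregate per-fold metric records into mean and t-based CI.

    CI = mean ± t_{k-1, (1+level)/2} · sd / sqrt(k), clipped to each metric's
    valid range. A single record yields a degenerate CI equal to the mean.
    """
    if not records:
        raise ValueError("no fold records to summarize")
    folds = pd.DataFrame(records, columns=METRIC_NAMES)
    if folds.isna().any().any():
        raise ValueError("fold records contain missing metrics")
    mean = folds.mean()
    k = len(folds)
    if k >= 2:
        sd = folds.std(ddof=1)
        tq = stats.t.ppf(0.5 + ci_level / 2.0, df=k - 1)
        half = tq * sd / np.sqrt(k)
    else:
        half = pd.Series(0.0, index=folds.columns)
    lo = mean - half
    hi = mean + half
    for m, (a, b) in METRIC_RANGES.items():
        lo[m] = min(max(lo[m], a), b)
        hi[m] = min(max(hi[m], a), b)
    return MetricsSummary(folds=folds, mean=mean, ci_lo=lo, ci_hi=hi, ci_level=ci_level)
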