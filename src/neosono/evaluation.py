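"""Multi-class evaluation: confusion matrix, one-vs-rest metrics, ROC AUC.

All metrics live on [0, 1] internally; report renderers multiply by 100.
For a K-class problem each class is scored one-vs-rest: the class is the
positive, all others pooled as the negative, giving TP/FP/TN/FN from the
confusion matrix. The "Overall" row is the unweighted (macro) mean across
classes. AUC uses the Mann-Whitney rank-sum formulation with midranks for
ties, which equals the fraction of positive/negative pairs ordered
correctly (ties counting one half).

Zero denominators (possible in small cross-validation folds where a class
is never predicted) yield 0 with a warning rather than an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .density import CLASS_NAMES

__all__ = [
    "ConfusionMatrix",
    "OvRCounts",
    "EvaluationReport",
    "confusion_matrix",
    "confusion_from_row_percent",
    "one_vs_rest_counts",
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "f_measure",
    "roc_auc_ovr",
    "macro_summary",
    "evaluate_predictions",
    "cv_aggregate",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy",
                "f_measure", "auc")


class OvRCounts(NamedTuple):
    tp: float
    fp: float
    tn: float
    fn: float


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.class_names)
        if c.shape != (k, k):
            raise ValueError(f"counts shape {c.shape} != ({k}, {k})")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def row_percent(self) -> np.ndarray:
        """Row-normalised view in percent (rows sum to 100)."""
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(rows > 0, 100.0 * self.counts / rows, 0.0)
        return out


def confusion_matrix(
    true_labels: Sequence, predicted_labels: Sequence,
    class_names: Sequence[str] = CLASS_NAMES,
) -> ConfusionMatrix:
    """Tally counts[i][j] = #samples with true class i predicted as j."""
    names = tuple(class_names)
    index = {c: i for i, c in enumerate(names)}
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    k = len(names)
    counts = np.zeros((k, k), dtype=np.int64)
    for ti, pi in zip(t, p):
        if ti not in index or pi not in index:
            raise ValueError(f"unknown label in pair ({ti!r}, {pi!r})")
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts, names)


def confusion_from_row_percent(
    row_percent: np.ndarray,
    class_sizes: Sequence[int],
    class_names: Sequence[str] = CLASS_NAMES,
) -> ConfusionMatrix:
    """Reconstruct counts from a row-percent matrix and per-class sizes.

    Inverse of :meth:`ConfusionMatrix.row_percent`; entries are rounded to
    the nearest integer count.
    """
    rp = np.asarray(row_percent, dtype=float)
    sizes = np.asarray(class_sizes, dtype=float)[:, None]
    counts = np.rint(rp / 100.0 * sizes).astype(np.int64)
    return ConfusionMatrix(counts, tuple(class_names))


def one_vs_rest_counts(m: ConfusionMatrix, class_index: int) -> OvRCounts:
    """Collapse all other classes into the negative for one class."""
    c = np.asarray(m.counts, dtype=float)
    tp = c[class_index, class_index]
    fn = c[class_index].sum() - tp
    fp = c[:, class_index].sum() - tp
    tn = c.sum() - tp - fp - fn
    return OvRCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def sensitivity(c: OvRCounts) -> float:
    """Recall: TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: OvRCounts) -> float:
    """TN / (TN + FP)."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def accuracy(c: OvRCounts) -> float:
    """One-vs-rest accuracy: (TP + TN) / (TP + TN + FP + FN)."""
    return _ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn, "accuracy")


def precision(c: OvRCounts) -> float:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def f_measure(precision_value: float, sensitivity_value: float) -> float:
    """Harmonic mean of precision and sensitivity (symmetric)."""
    return _ratio(
        2.0 * precision_value * sensitivity_value,
        precision_value + sensitivity_value,
        "f_measure",
    )


def roc_auc_ovr(
    probabilities: np.ndarray,
    true_labels: Sequence,
    class_index: int,
    class_names: Sequence[str] = CLASS_NAMES,
) -> float:
    """One-vs-rest AUC by the Mann-Whitney rank sum with midranks.

    Equals the probability that a random positive outranks a random
    negative in the class's predicted score (ties count 1/2). Returns NaN
    with a warning when the class is absent from the truth.
    """
    proba = np.asarray(probabilities, dtype=float)
    y = np.asarray(true_labels)
    pos = y == class_names[class_index]
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn(
            f"AUC undefined for class {class_names[class_index]!r} "
            f"(missing positives or negatives)", stacklevel=2,
        )
        return float("nan")
    scores = proba[:, class_index]
    ranks = rankdata(scores)  # midranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def macro_summary(per_class: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted mean of each metric across classes (the Overall row)."""
    metrics = next(iter(per_class.values())).keys()
    return {
        m: float(np.nanmean([per_class[c][m] for c in per_class]))
        for m in metrics
    }


@dataclass
class EvaluationReport:
    """Per-class one-vs-rest metrics, their macro means, and the matrix."""

    matrix: ConfusionMatrix
    per_class: dict[str, dict[str, float]]
    overall: dict[str, float]

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        rows = {}
        for cls, metrics in self.per_class.items():
            rows[cls] = dict(metrics)
        rows["Overall"] = dict(self.overall)
        df = pd.DataFrame(rows).T
        if percent:
            for col in df.columns:
                if col != "auc":
                    df[col] = df[col] * 100.0
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_names": list(self.matrix.class_names),
                "confusion_counts": self.matrix.counts.tolist(),
                "confusion_row_percent": self.matrix.row_percent().tolist(),
                "per_class": self.per_class,
                "overall": self.overall,
            },
            indent=2,
            allow_nan=True,
        )


def evaluate_predictions(
    true_labels: Sequence,
    predicted_labels: Sequence,
    class_names: Sequence[str] = CLASS_NAMES,
    probabilities: np.ndarray | None = None,
) -> EvaluationReport:
    """Full report from labels (and optionally scores, for AUC)."""
    m = confusion_matrix(true_labels, predicted_labels, class_names)
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(m.class_names):
        counts = one_vs_rest_counts(m, i)
        p = precision(counts)
        r = sensitivity(counts)
        row = {
            "sensitivity": r,
            "specificity": specificity(counts),
            "precision": p,
            "accuracy": accuracy(counts),
            "f_measure": f_measure(p, r),
        }
        if probabilities is not None:
            row["auc"] = roc_auc_ovr(probabilities, true_labels, i, m.class_names)
        per_class[cls] = row
    return EvaluationReport(m, per_class, macro_summary(per_class))


def cv_aggregate(per_fold_reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Mean and sample sd of each metric per class and overall across folds.

    Returns a tidy frame with columns (metric, class, mean, sd); metrics
    are on [0, 1] (AUC included). Overall is the macro mean within each
    fold, aggregated across folds like any class column.
    """
    if len(per_fold_reports) < 2:
        raise ValueError("need at least two folds to aggregate")
    class_names = list(per_fold_reports[0].matrix.class_names) + ["Overall"]
    metrics = list(next(iter(per_fold_reports[0].per_class.values())).keys())
    rows = []
    for metric in metrics:
        for cls in class_names:
            vals = []
            for rep in per_fold_reports:
                src = rep.overall if cls == "Overall" else rep.per_class[cls]
                vals.append(src[metric])
            vals = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "metric": metric,
                    "class": cls,
                    "mean": float(np.nanmean(vals)),
                    "sd": float(np.nanstd(vals, ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def format_cv_table(agg: pd.DataFrame) -> pd.DataFrame:
    """Render the CV aggregate as 'mean ± sd' percent strings per class."""
    def fmt(row):
        scale = 1.0 if row["metric"] == "auc" else 100.0
        unit = "" if row["metric"] == "auc" else "%"
        return f"{row['mean'] * scale:.2f} ± {row['sd'] * scale:.2f}{unit}"

    out = agg.copy()
    out["value"] = out.apply(fmt, axis=1)
    return out.pivot(index="metric", columns="class", values="value")
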