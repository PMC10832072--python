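"""Evaluation: confusion matrix, per-class P/R/F1, macro and weighted means.

The aggregates follow the usual multiclass definitions: the macro average of
a score is its unweighted mean over classes,

    macro = (1/K) * sum_c score_c,

and the weighted average weights each class by its share of the samples,

    weighted = sum_c (n_c / n) * score_c.

The relative performance improvement rate between two models is
``100 * (new - previous) / previous`` percent.  Scores are kept at full
precision internally; display rounds scores to 4 decimals and rates to 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "macro_average",
    "weighted_average",
    "relative_improvement",
    "evaluate_predictions",
    "comparison_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
            raise ValueError("confusion matrix must be square and nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def support(self) -> np.ndarray:
        """Per-class true counts (row sums)."""
        return self.counts.sum(axis=1)


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    """Count matrix with ``counts[i, j] = #{true i predicted j}``."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label lists must have equal length")
    if t.size and (t.max() >= n_classes or p.max() >= n_classes or t.min() < 0 or p.min() < 0):
        raise ValueError("labels must lie in [0, n_classes)")
    counts = np.bincount(t * n_classes + p, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts=counts.reshape(n_classes, n_classes))


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    bad = den == 0
    if np.any(bad):
        warnings.warn(
            f"zero denominator in {what} for class(es) {np.flatnonzero(bad).tolist()}; "
            "reporting 0",
            stacklevel=3,
        )
    np.divide(num, den, out=out, where=~bad)
    return out


def per_class_metrics(
    cm: ConfusionMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (precision, recall, F1) from a confusion matrix.

    Precision divides the diagonal by column sums, recall by row sums, and
    F1 is their harmonic mean; a zero denominator yields 0 with a warning
    rather than NaN, so degenerate small test sets still produce reports.
    """
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    tp = np.diag(counts).astype(float)
    precision = _safe_div(tp, counts.sum(axis=0), "precision")
    recall = _safe_div(tp, counts.sum(axis=1), "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    return precision, recall, f1


def macro_average(scores) -> float:
    """Unweighted arithmetic mean of per-class scores."""
    return float(np.mean(np.asarray(scores, dtype=float)))


def weighted_average(scores, counts) -> float:
    """Class-count-weighted mean ``sum_c (n_c / n) * score_c``."""
    scores = np.asarray(scores, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("counts must be nonnegative with a positive total")
    return float(np.sum(counts / counts.sum() * scores))


def relative_improvement(new: float, previous: float) -> float:
    """Relative performance improvement rate, in percent."""
    if previous <= 0:
        raise ValueError("previous performance must be positive")
    return 100.0 * (new - previous) / previous


@dataclass
class MetricsReport:
    """Full evaluation of one model on one test set."""

    cm: ConfusionMatrix
    class_names: list[str] = field(default_factory=list)
    weight_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = self.cm.n_classes
        if not self.class_names:
            self.class_names = [f"class{i}" for i in range(k)]
        if len(self.class_names) != k:
            raise ValueError("class_names length must match the matrix")
        if self.weight_counts is None:
            # weighted averages default to the evaluation-set class counts
            self.weight_counts = self.cm.support
        self.precision, self.recall, self.f1 = per_class_metrics(self.cm)

    @property
    def accuracy(self) -> float:
        return self.cm.accuracy

    def macro(self, metric: str) -> float:
        return macro_average(getattr(self, metric))

    def weighted(self, metric: str) -> float:
        return weighted_average(getattr(self, metric), self.weight_counts)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                name: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "support": int(self.cm.support[i]),
                }
                for i, name in enumerate(self.class_names)
            },
            "macro": {m: self.macro(m) for m in ("precision", "recall", "f1")},
            "weighted": {m: self.weighted(m) for m in ("precision", "recall", "f1")},
            "confusion": self.cm.counts.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_predictions(
    true_labels,
    predicted_labels,
    n_classes: int,
    class_names: list[str] | None = None,
    weight_counts=None,
) -> MetricsReport:
    """Build a :class:`MetricsReport` from label lists."""
    cm = confusion_matrix(true_labels, predicted_labels, n_classes)
    return MetricsReport(
        cm=cm,
        class_names=class_names or [],
        weight_counts=None if weight_counts is None else np.asarray(weight_counts),
    )


def comparison_report(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Side-by-side comparison grid across named models.

    Rows: accuracy, then per-class / weighted-average / macro-average rows
    for precision, recall and F1; one column block per model.  Values are
    full precision; round for display.
    """
    if not reports:
        raise ValueError("at least one report is required")
    ks = {r.cm.n_classes for r in reports.values()}
    if len(ks) > 1:
        raise ValueError("all reports must share the same class count")
    first = next(iter(reports.values()))
    rows = (
        ["accuracy"]
        + first.class_names
        + ["weighted average", "macro average"]
    )
    data: dict[tuple[str, str], list[float]] = {}
    for name, rep in reports.items():
        for metric in ("precision", "recall", "f1"):
            col = [rep.accuracy if metric == "precision" else np.nan]
            col += list(getattr(rep, metric))
            col += [rep.weighted(metric), rep.macro(metric)]
            data[(metric, name)] = col
    frame = pd.DataFrame(data, index=rows)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["metric", "model"])
    return frame
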