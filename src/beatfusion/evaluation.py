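"""Confusion-matrix construction and per-class / aggregate metrics.

Per-class metrics are one-vs-rest: the class is treated as positive and all
others as negative, giving TP/TN/FP/FN from which accuracy, recall,
precision, specificity and F1 follow:

    Accuracy    = (TP + TN) / (TP + TN + FP + FN)
    Recall      = TP / (TP + FN)
    Precision   = TP / (TP + FP)
    Specificity = TN / (TN + FP)
    F1          = 2 · P · R / (P + R)

Zero-denominator cases return 0 and are flagged so aggregate means stay
defined.  Aggregates are overall accuracy (trace / total) plus unweighted
macro means by default; support-weighted means are available via a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix", "one_vs_rest_counts", "compute_metrics"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (k, k) ints; rows = true, columns = predicted
    class_vocabulary: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_vocabulary)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be (k, k) for k classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("true\\pred," + ",".join(self.class_vocabulary) + "\n")
            for label, row in zip(self.class_vocabulary, self.counts):
                fh.write(label + "," + ",".join(str(int(v)) for v in row) + "\n")


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    aggregate: dict[str, float]
    zero_denominator_flags: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "per_class": self.per_class,
                "aggregate": self.aggregate,
                "zero_denominator_flags": self.zero_denominator_flags,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    def to_text(self) -> str:
        """Plain-text table: one metric row per line, one column per class."""
        classes = list(self.per_class)
        lines = ["Per-class performance".ljust(16) + "".join(c.rjust(10) for c in classes)]
        for metric in ("accuracy", "specificity", "precision", "recall", "f1"):
            row = metric.capitalize().ljust(16)
            row += "".join(f"{100 * self.per_class[c][metric]:10.2f}" for c in classes)
            lines.append(row)
        lines.append(
            "Aggregate: "
            + ", ".join(f"{k}={100 * v:.2f}%" for k, v in self.aggregate.items())
        )
        return "\n".join(lines)


def confusion_matrix(y_true: list[str], y_pred: list[str], vocab: list[str]) -> ConfusionMatrix:
    """counts[i][j] = number of beats with true vocab[i] predicted vocab[j]."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(vocab)}
    counts = np.zeros((len(vocab), len(vocab)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside vocabulary: true={t!r}, pred={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(vocab))


def one_vs_rest_counts(cm: ConfusionMatrix, class_index: int) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) treating `class_index` as positive."""
    c = cm.counts
    if not 0 <= class_index < len(cm.class_vocabulary):
        raise IndexError("class_index out of range")
    tp = int(c[class_index, class_index])
    fn = int(c[class_index].sum()) - tp
    fp = int(c[:, class_index].sum()) - tp
    tn = cm.total - tp - fn - fp
    return tp, tn, fp, fn


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix, weighted: bool = False) -> MetricsReport:
    """Per-class one-vs-rest metrics plus overall accuracy and macro means."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    zero_flags: dict[str, list[str]] = {}
    supports = []
    for i, label in enumerate(cm.class_vocabulary):
        tp, tn, fp, fn = one_vs_rest_counts(cm, i)
        flags: list[str] = []
        precision = _safe_div(tp, tp + fp, flags, "precision")
        recall = _safe_div(tp, tp + fn, flags, "recall")
        per_class[label] = {
            "accuracy": (tp + tn) / cm.total,
            "precision": precision,
            "recall": recall,
            "specificity": _safe_div(tn, tn + fp, flags, "specificity"),
            "f1": _safe_div(2 * precision * recall, precision + recall, flags, "f1"),
        }
        if flags:
            zero_flags[label] = flags
        supports.append(tp + fn)
    supports = np.asarray(supports, dtype=np.float64)
    if weighted and supports.sum() > 0:
        w = supports / supports.sum()
    else:
        w = np.full(len(supports), 1.0 / len(supports))
    prefix = "weighted" if weighted else "macro"
    aggregate = {
        "overall_accuracy": float(np.trace(cm.counts) / cm.total),
        f"{prefix}_f1": float(sum(w[i] * per_class[c]["f1"] for i, c in enumerate(cm.class_vocabulary))),
        f"{prefix}_precision": float(sum(w[i] * per_class[c]["precision"] for i, c in enumerate(cm.class_vocabulary))),
        f"{prefix}_recall": float(sum(w[i] * per_class[c]["recall"] for i, c in enumerate(cm.class_vocabulary))),
        f"{prefix}_specificity": float(sum(w[i] * per_class[c]["specificity"] for i, c in enumerate(cm.class_vocabulary))),
    }
    return MetricsReport(per_class, aggregate, zero_flags)
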