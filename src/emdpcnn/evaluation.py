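"""Confusion matrices and the derived classification metrics.

The confusion-matrix convention here is rows = predicted class, columns
= actual class.  For K classes each class is scored one-vs-rest:
``TP = counts[c][c]``, ``FP`` sums the rest of row c, ``FN`` the rest of
column c and ``TN`` is everything else.  Six metrics follow —
specificity, sensitivity, precision, accuracy, recall and F1 — with
sensitivity and recall identical by definition; macro values are
unweighted class means.  Ratios with a zero denominator are reported as
0 with a flag rather than NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix", "metrics"]

METRIC_NAMES = ("specificity", "sensitivity", "precision", "accuracy", "recall", "f1")


@dataclass
class ConfusionMatrix:
    """K x K count table; ``counts[p][a]`` = predicted p, actual a."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path, class_names: list[str] | None = None) -> None:
        names = class_names or [f"class{i}" for i in range(self.n_classes)]
        lines = ["predicted\\actual\t" + "\t".join(names)]
        for i, row in enumerate(self.counts):
            lines.append(names[i] + "\t" + "\t".join(str(v) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics, all on the [0, 1] scale."""

    per_class: dict[str, np.ndarray]
    macro: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def as_percent(self) -> dict[str, float]:
        """Macro metrics as percentages rounded to 2 decimals."""
        return {k: round(100.0 * v, 2) for k, v in self.macro.items()}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
            "macro": self.macro,
            "macro_percent": self.as_percent(),
            "flags": self.flags,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def confusion_matrix(predicted, actual, K: int) -> ConfusionMatrix:
    """Tally ``counts[p][a] = #{i : predicted_i = p and actual_i = a}``."""
    predicted = np.asarray(predicted, dtype=int)
    actual = np.asarray(actual, dtype=int)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    if predicted.size and (
        predicted.min() < 0 or actual.min() < 0
        or predicted.max() >= K or actual.max() >= K
    ):
        raise ValueError(f"labels must lie in [0, {K})")
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (predicted, actual), 1)
    return ConfusionMatrix(counts=counts)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest metrics per class plus unweighted macro averages."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    K = cm.n_classes
    c = cm.counts.astype(float)
    total = c.sum()
    tp = np.diag(c)
    fp = c.sum(axis=1) - tp
    fn = c.sum(axis=0) - tp
    tn = total - tp - fp - fn

    flags: list[str] = []

    def ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
        out = np.zeros(K)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        for k in np.nonzero(~ok)[0]:
            flags.append(f"{name}_class{k}_zero_denominator")
        return out

    specificity = ratio(tn, tn + fp, "specificity")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    precision = ratio(tp, tp + fp, "precision")
    accuracy = (tp + tn) / total
    recall = sensitivity.copy()
    f1 = ratio(2 * precision * recall, precision + recall, "f1")

    per_class = {
        "specificity": specificity,
        "sensitivity": sensitivity,
        "precision": precision,
        "accuracy": accuracy,
        "recall": recall,
        "f1": f1,
    }
    macro = {k: float(np.mean(v)) for k, v in per_class.items()}
    return MetricsReport(per_class=per_class, macro=macro, flags=flags)
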