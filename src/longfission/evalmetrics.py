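"""Confusion matrices and classification metrics for the two-class problem.

Class 0 is ``longitudinal_division`` (cells dividing along their long axis,
so they widen), class 1 is ``other_division`` (transverse or no visible
septum).  Metrics are reported as percentages to four decimal places, the
precision used throughout for precision/recall/F1 tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

CLASS_NAMES = {0: "longitudinal_division", 1: "other_division"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 contingency table; ``counts[i, j]`` = items of true class i predicted j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("confusion matrix must be 2x2 with non-negative counts")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp_fp_fn_tn(self, positive: int) -> tuple[int, int, int, int]:
        """TP/FP/FN/TN with ``positive`` as the positive class."""
        if positive not in (0, 1):
            raise ValueError("positive class must be 0 or 1")
        neg = 1 - positive
        c = self.counts
        return (
            int(c[positive, positive]),
            int(c[neg, positive]),
            int(c[positive, neg]),
            int(c[neg, neg]),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Per-class precision/recall/F1 plus overall accuracy, all in percent."""

    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    accuracy: float

    def as_rows(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for cls in sorted(self.precision):
            rows.append(
                {
                    "class": CLASS_NAMES.get(cls, str(cls)),
                    "precision": self.precision[cls],
                    "recall": self.recall[cls],
                    "f1": self.f1[cls],
                }
            )
        return rows


def confusion(preds: Sequence[int], labels: Sequence[int]) -> ConfusionMatrix:
    """Tally every (label, prediction) pair into a 2x2 matrix.

    Raises on length mismatch or labels/predictions outside {0, 1}.
    """
    p = np.asarray(preds, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError(f"preds and labels must be equal-length 1-D, got {p.shape} vs {y.shape}")
    if p.size:
        ids = np.union1d(p, y)
        if ids[0] < 0 or ids[-1] > 1:
            raise ValueError("class ids must be in {0, 1}")
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (y, p), 1)
    return ConfusionMatrix(counts)


def precision_recall_f1(cm: ConfusionMatrix, positive: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), in percent.

    Degenerate denominators yield 0: no predicted positives -> P = 0, no
    actual positives -> R = 0, and F1 = 0 whenever there is no true positive.
    """
    tp, fp, fn, _ = cm.tp_fp_fn_tn(positive)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return 100.0 * p, 100.0 * r, 100.0 * f1


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified items, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class metrics with each class taken as positive in turn."""
    prec: dict[int, float] = {}
    rec: dict[int, float] = {}
    f1s: dict[int, float] = {}
    for cls in (0, 1):
        p, r, f = precision_recall_f1(cm, cls)
        prec[cls], rec[cls], f1s[cls] = p, r, f
    return MetricsReport(precision=prec, recall=rec, f1=f1s, accuracy=accuracy(cm))


def render_report(rep: MetricsReport) -> str:
    """Plain-text table, four-decimal percentages (half-even rounding)."""
    lines = [f"{'class':<24}{'precision':>12}{'recall':>12}{'f1':>12}"]
    for row in rep.as_rows():
        lines.append(
            f"{row['class']:<24}{row['precision']:>11.4f}%{row['recall']:>11.4f}%{row['f1']:>11.4f}%"
        )
    lines.append(f"overall accuracy: {rep.accuracy:.4f}%")
    return "\n".join(lines)


def report_to_csv(rep: MetricsReport, path) -> None:
    import pandas as pd

    rows = rep.as_rows()
    df = pd.DataFrame(rows)
    for col in ("precision", "recall", "f1"):
        df[col] = df[col].map(lambda v: f"{v:.4f}")
    df.loc[len(df)] = {"class": "overall_accuracy", "precision": f"{rep.accuracy:.4f}", "recall": "", "f1": ""}
    df.to_csv(path, index=False)
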