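"""Evaluation battery for multi-class staging: confusion matrix,
per-class precision/recall/F1, overall accuracy, and Cohen's kappa.

Matrix convention: rows are the clinical (ground-truth) stages, columns the
predicted stages.  Kappa is (p_o − p_e)/(1 − p_e) with the expected
agreement p_e from the products of row and column marginals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Square non-negative integer count matrix with ordered class labels."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix must contain at least one count")

    @classmethod
    def from_labels(
        cls,
        true: Sequence[str],
        predicted: Sequence[str],
        classes: Sequence[str] | None = None,
    ) -> "ConfusionMatrix":
        true = list(true)
        predicted = list(predicted)
        if len(true) != len(predicted):
            raise ValueError("true and predicted label sequences must have equal length")
        if classes is None:
            classes = sorted(set(true) | set(predicted))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(true, predicted):
            counts[index[t], index[p]] += 1
        return cls(tuple(classes), counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def evaluate(cm: ConfusionMatrix) -> dict:
    """All evaluation indices from one confusion matrix.

    Returns a dict with ``accuracy``, ``kappa``, a ``per_class`` mapping of
    precision/recall/f1, and macro averages.  A class never predicted gets
    precision 0 (flagged in the log); if expected agreement is 1 the kappa
    denominator vanishes and kappa is reported as 0.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    diag = np.diag(counts)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)

    accuracy = float(diag.sum() / total)
    p_e = float(np.sum(row_sums * col_sums) / total**2)
    if abs(1.0 - p_e) < 1e-15:
        logger.debug("expected agreement is 1: kappa undefined, reported as 0")
        kappa = 0.0
    else:
        kappa = float((accuracy - p_e) / (1.0 - p_e))

    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(cm.classes):
        if col_sums[i] == 0:
            logger.debug("class %s never predicted: precision set to 0", cls)
            precision = 0.0
        else:
            precision = float(diag[i] / col_sums[i])
        recall = float(diag[i] / row_sums[i]) if row_sums[i] > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}

    macro = {
        key: float(np.mean([per_class[c][key] for c in cm.classes]))
        for key in ("precision", "recall", "f1")
    }
    return {
        "accuracy": accuracy,
        "kappa": kappa,
        "per_class": per_class,
        "macro": macro,
        "total": int(total),
    }


def format_report(cm: ConfusionMatrix, metrics: dict | None = None) -> str:
    """Human-readable table: counts with per-class precision/recall/F1
    columns and an accuracy/kappa footer."""
    if metrics is None:
        metrics = evaluate(cm)
    width = max(9, max(len(c) for c in cm.classes) + 2)
    header = (
        f"{'':>{width}}"
        + "".join(f"{c:>{width}}" for c in cm.classes)
        + f"{'Precision':>11}{'Recall':>9}{'F1':>7}"
    )
    lines = [header]
    for i, cls in enumerate(cm.classes):
        pc = metrics["per_class"][cls]
        lines.append(
            f"{cls:>{width}}"
            + "".join(f"{int(n):>{width}}" for n in cm.counts[i])
            + f"{pc['precision']:>11.2f}{pc['recall']:>9.2f}{pc['f1']:>7.2f}"
        )
    lines.append(f"Accuracy: {metrics['accuracy']:.4f}   Cohen's kappa: {metrics['kappa']:.2f}")
    return "\n".join(lines)


def metrics_to_json(cm: ConfusionMatrix, metrics: dict | None = None) -> str:
    """Deterministic JSON serialization of a matrix and its metrics."""
    if metrics is None:
        metrics = evaluate(cm)
    payload = {
        "classes": list(cm.classes),
        "counts": cm.counts.tolist(),
        **metrics,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
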