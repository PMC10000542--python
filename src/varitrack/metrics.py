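"""Evaluation metrics of the recognition pipeline.

Five quantities summarize a run: accuracy and precision of the record-level
normal/abnormal decisions, the pattern-verification count (flagged-unknown
patterns confirmed against ground truth), the mean per-record variance, and
the wall-clock verification time.  Verification time is hardware-dependent
and is reported only, never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .pattern import PartitionResult

__all__ = [
    "MetricsBundle",
    "confusion_counts",
    "confusion_metrics",
    "summarize_additional_observations",
]


@dataclass
class MetricsBundle:
    """The five reported metrics (accuracy/precision as fractions in [0, 1])."""

    accuracy: float
    precision: float
    pattern_verification: int
    mean_variance: float
    verification_time: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    def to_json(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "pattern_verification": self.pattern_verification,
            "mean_variance": self.mean_variance,
            "verification_time": self.verification_time,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_counts(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for 0/1 label arrays of equal length."""
    predicted = np.asarray(predicted).astype(int).ravel()
    truth = np.asarray(truth).astype(int).ravel()
    if predicted.shape != truth.shape:
        raise ValueError(
            f"predicted length {predicted.shape} != truth length {truth.shape}"
        )
    bad = set(np.unique(predicted)) | set(np.unique(truth))
    if not bad <= {0, 1}:
        raise ValueError(f"labels must be 0/1, got values {sorted(bad)}")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    return tp, fp, tn, fn


def confusion_metrics(
    predicted: np.ndarray,
    truth: np.ndarray,
    variances: Iterable[float] | None = None,
    verification_time: float | None = None,
) -> MetricsBundle:
    """Accuracy, precision and companion metrics from 0/1 predictions vs truth.

    ``accuracy = (TP+TN)/(TP+TN+FP+FN)``; ``precision = TP/(TP+FP)`` with 0/0
    defined as 0.  The pattern-verification count is TP: flagged patterns
    confirmed by the ground truth.  ``mean_variance`` averages the supplied
    per-record variance values (0 when none are supplied).
    """
    tp, fp, tn, fn = confusion_counts(predicted, truth)
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    mean_var = float(np.mean(list(variances))) if variances is not None else 0.0
    return MetricsBundle(
        accuracy=accuracy,
        precision=precision,
        pattern_verification=tp,
        mean_variance=mean_var,
        verification_time=verification_time,
        sensitivity=sensitivity,
        specificity=specificity,
    )


def summarize_additional_observations(partition: PartitionResult) -> dict[str, int]:
    """Per-subject count of augmentation flags (additional NHR/RPDE/DFA needed).

    The counts sum to |Q|: every unknown record demands the additional
    observations at the next sensing instance.
    """
    counts: dict[str, int] = {}
    for a in partition.assessments:
        counts.setdefault(a.subject_id, 0)
        if a.augmentation:
            counts[a.subject_id] += 1
    return counts
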