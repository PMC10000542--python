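"""Progression stage: per-subject variance aggregation and decisions.

"Variance" here is the method's deviation statistic, not a second moment: the
difference between the previously acquired data and the current observation.
Two modes compute a per-record variance series for a subject:

``da``
    successive absolute differences of the designated progression feature
    (default ``Jitter:RAP``) on the normalized scale — length n-1;
``model``
    ``|score_t - reference score|``, where the scores come from a trained
    recurrent learner and the reference score is the learner's output on the
    subject's stored-profile mean vector.

A subject is *progressive* iff the aggregated score Z — the maximum of the
series over the evaluation window, mean aggregation optional — strictly
exceeds the decision threshold (default 0.06, applied on normalized units).
A cohort-level retraining trigger fires when the unknown fraction
|Q| / (|Q| + |V|) of the partition exceeds a configurable fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import PatientSequence
from .learner import ModelParams, forward_sequence
from .pattern import PartitionResult, StoredProfile

__all__ = [
    "VarianceSeries",
    "ProgressionReport",
    "variance_series",
    "progression_score",
    "retrain_trigger",
    "progression_report_cohort",
    "ProgressionDetector",
]

DEFAULT_PROGRESSION_FEATURE = "Jitter:RAP"
DEFAULT_PROGRESSION_THRESHOLD = 0.06


@dataclass
class VarianceSeries:
    """Nonnegative per-record variance values for one subject."""

    subject_id: str
    values: np.ndarray
    feature: str
    mode: str  # "da" | "model"


@dataclass
class ProgressionReport:
    """Per-subject progression decision.

    ``decision`` is ``"progressive"`` iff ``score > threshold`` (strict).
    ``retrain_recommended`` mirrors the cohort-level trigger when an unknown
    fraction is available.
    """

    subject_id: str
    score: float
    decision: str
    threshold: float
    series: VarianceSeries
    unknown_fraction: float | None = None
    retrain_recommended: bool | None = None

    def to_json(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "score": self.score,
            "decision": self.decision,
            "threshold": self.threshold,
            "mode": self.series.mode,
            "feature": self.series.feature,
            "n_values": int(len(self.series.values)),
            "unknown_fraction": self.unknown_fraction,
            "retrain_recommended": self.retrain_recommended,
        }


def variance_series(
    sequence: PatientSequence,
    mode: str = "da",
    feature: str = DEFAULT_PROGRESSION_FEATURE,
    params: ModelParams | None = None,
    profile: StoredProfile | None = None,
    feature_names: Sequence[str] | None = None,
) -> VarianceSeries:
    """Per-record variance of one normalized sequence.

    ``da`` mode needs only the sequence; ``model`` mode needs trained
    ``params`` (and a stored ``profile`` supplying the per-subject reference
    vector — its running mean of accepted records).
    """
    if mode == "da":
        vals = sequence.feature_matrix([feature])[:, 0]
        series = np.abs(np.diff(vals))
        return VarianceSeries(sequence.subject_id, series, feature, mode)
    if mode == "model":
        if params is None:
            raise RuntimeError("model-mode variance requires trained parameters")
        if profile is None:
            raise RuntimeError("model-mode variance requires a stored profile")
        names = tuple(feature_names) if feature_names else profile.feature_names
        X = sequence.feature_matrix(names)
        _, scores = forward_sequence(params, X)
        ref_vec = profile.mean(sequence.subject_id)
        _, ref_score = forward_sequence(params, ref_vec[None, :])
        series = np.abs(scores - ref_score[0])
        return VarianceSeries(sequence.subject_id, series, feature, mode)
    raise ValueError(f"unknown variance mode {mode!r}")


def progression_score(
    series: VarianceSeries,
    threshold: float = DEFAULT_PROGRESSION_THRESHOLD,
    aggregate: str = "max",
) -> ProgressionReport:
    """Aggregate a variance series into Z and decide progression (Z > threshold)."""
    if len(series.values) == 0:
        raise ValueError(f"empty variance series for subject {series.subject_id}")
    if aggregate == "max":
        z = float(np.max(series.values))
    elif aggregate == "mean":
        z = float(np.mean(series.values))
    else:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    decision = "progressive" if z > threshold else "stable"
    return ProgressionReport(series.subject_id, z, decision, threshold, series)


def retrain_trigger(partition: PartitionResult, threshold: float = 0.2) -> bool:
    """True iff the unknown fraction |Q|/(|Q|+|V|) strictly exceeds ``threshold``."""
    if not partition.Q and not partition.V:
        raise ValueError("partition holds no eligible records")
    return partition.unknown_fraction > threshold


def progression_report_cohort(
    sequences: Sequence[PatientSequence],
    mode: str = "da",
    feature: str = DEFAULT_PROGRESSION_FEATURE,
    threshold: float = DEFAULT_PROGRESSION_THRESHOLD,
    aggregate: str = "max",
    params: ModelParams | None = None,
    profile: StoredProfile | None = None,
    partition: PartitionResult | None = None,
    retrain_fraction: float = 0.2,
    feature_names: Sequence[str] | None = None,
) -> list[ProgressionReport]:
    """One deterministic :class:`ProgressionReport` per subject.

    When a partition is supplied, each report also carries the subject's
    unknown fraction and the cohort retraining recommendation.
    """
    retrain = None
    if partition is not None:
        retrain = retrain_trigger(partition, retrain_fraction)
    reports = []
    for seq in sequences:
        series = variance_series(
            seq, mode=mode, feature=feature, params=params, profile=profile,
            feature_names=feature_names,
        )
        report = progression_score(series, threshold, aggregate)
        if partition is not None:
            labels = partition.labels(seq.subject_id)
            eligible = max(len(labels) - 1, 1)
            report.unknown_fraction = float(labels.sum() / eligible)
            report.retrain_recommended = retrain
        reports.append(report)
    return reports


def reports_to_frame(reports: Sequence[ProgressionReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_json() for r in reports])


class ProgressionDetector(BaseEstimator):
    """Estimator wrapper: subject-level progressive/stable decisions.

    Parameters mirror :func:`progression_report_cohort`; ``predict`` returns
    one 0/1 flag per sequence (1 = progressive).
    """

    def __init__(
        self,
        threshold: float = DEFAULT_PROGRESSION_THRESHOLD,
        feature: str = DEFAULT_PROGRESSION_FEATURE,
        mode: str = "da",
        aggregate: str = "max",
    ):
        self.threshold = threshold
        self.feature = feature
        self.mode = mode
        self.aggregate = aggregate

    def report(
        self,
        sequences: Sequence[PatientSequence],
        params: ModelParams | None = None,
        profile: StoredProfile | None = None,
        partition: PartitionResult | None = None,
    ) -> list[ProgressionReport]:
        return progression_report_cohort(
            sequences,
            mode=self.mode,
            feature=self.feature,
            threshold=self.threshold,
            aggregate=self.aggregate,
            params=params,
            profile=profile,
            partition=partition,
        )

    def predict(self, sequences: Sequence[PatientSequence]) -> np.ndarray:
        reports = self.report(sequences)
        return np.array([1 if r.decision == "progressive" else 0 for r in reports])
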