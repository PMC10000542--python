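"""Pattern recognition stage: sequence encoding and difference-amplitude partition.

Each subject's normalized observation sequence is swept in time order and
every record with a predecessor is classified by its *difference amplitude*
(DA): the absolute successive difference of each normalized feature.  On the
common [0, 1] scale the expected fluctuation band of the core voice measures
(Jitter(%) and Shimmer by default) is 0.4-0.6; a core DA beyond the upper
threshold marks the record as *unknown* (set Q) and raises an augmentation
flag requiring the additional NHR/RPDE/DFA observations at the next sensing
instance.  Everything else is *normal* (set V) and feeds the stored profile
and the training buffer of the recurrent learner.

The similarity of a record to its predecessor is phi = 1 - max(core DA), so a
record is normal iff phi >= 1 - upper.  A sequence-level novelty score is the
chain-factorized product of the clipped core DAs of its flagged records; it
is logged for inspection, never used for decisions.

A lightweight recurrent encoder is also provided: A_0 = 0 and
A_a = g(W x_a + S A_{a-1}) elementwise with g the logistic function, where S
weighs the stored data against the fresh observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .cohort import ObservationRecord, PatientSequence

__all__ = [
    "DEFAULT_CORE_FEATURES",
    "EncodedState",
    "DifferenceAmplitude",
    "RecordAssessment",
    "PartitionResult",
    "StoredProfile",
    "encode_sequence",
    "compute_da",
    "classify_record",
    "similarity",
    "novelty_score",
    "partition_cohort",
    "DifferencePartitioner",
]

DEFAULT_CORE_FEATURES: tuple[str, ...] = ("Jitter(%)", "Shimmer")


@dataclass
class EncodedState:
    """Hidden encoding ``A`` at step ``alpha`` (``A = 0`` at ``alpha = 0``)."""

    alpha: int
    A: np.ndarray


def encode_sequence(
    sequence: PatientSequence | np.ndarray,
    W: np.ndarray,
    S: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> list[EncodedState]:
    """Unroll the recognition recurrence over a normalized sequence.

    ``A_0 = 0``; ``A_a = logistic(W x_a + S A_{a-1})``.  Returns the states
    for ``alpha = 0 .. n`` (the initial zero state plus one state per record).
    """
    if isinstance(sequence, PatientSequence):
        if feature_names is None:
            feature_names = list(sequence.records[0].features)
        X = sequence.feature_matrix(feature_names)
    else:
        X = np.asarray(sequence, dtype=float)
    W = np.asarray(W, dtype=float)
    S = np.asarray(S, dtype=float)
    H = W.shape[0]
    if W.ndim != 2 or S.shape != (H, H) or (len(X) and X.shape[1] != W.shape[1]):
        raise ValueError(
            f"shape mismatch: W {W.shape}, S {S.shape}, features {X.shape[1:] if X.ndim > 1 else X.shape}"
        )
    A = np.zeros(H)
    states = [EncodedState(0, A.copy())]
    for alpha, x in enumerate(X, start=1):
        A = expit(W @ x + S @ A)
        states.append(EncodedState(alpha, A.copy()))
    return states


@dataclass
class DifferenceAmplitude:
    """Per-feature absolute successive difference on the normalized scale."""

    per_feature: dict[str, float]
    core_features: tuple[str, ...]

    @property
    def core_max(self) -> float:
        return max(self.per_feature[name] for name in self.core_features)


def compute_da(
    prev: ObservationRecord,
    curr: ObservationRecord,
    core_features: Sequence[str] = DEFAULT_CORE_FEATURES,
) -> DifferenceAmplitude:
    """Difference amplitude between two successive normalized records."""
    missing = [n for n in core_features if n not in curr.features or n not in prev.features]
    if missing:
        raise KeyError(f"core features missing from records: {missing}")
    per_feature = {
        name: abs(curr.features[name] - prev.features[name])
        for name in curr.features
        if name in prev.features
    }
    return DifferenceAmplitude(per_feature, tuple(core_features))


def classify_record(
    da: DifferenceAmplitude, lower: float = 0.4, upper: float = 0.6
) -> tuple[str, bool]:
    """Classify a record by its core DA against the (lower, upper) band.

    A record is *unknown* iff any core-feature DA strictly exceeds ``upper``;
    the augmentation flag (NHR/RPDE/DFA required at the next instance) is
    raised exactly for unknown records.  Core DAs inside the band
    ``[lower, upper]`` and below ``lower`` are both normal: the band is the
    expected fluctuation range, not a decision boundary of its own.
    """
    if not 0 <= lower < upper:
        raise ValueError(f"thresholds must satisfy 0 <= lower < upper, got {lower}, {upper}")
    unknown = da.core_max > upper
    return ("unknown", True) if unknown else ("normal", False)


def similarity(da: DifferenceAmplitude) -> float:
    """phi = 1 - max(core DA); a record is normal iff phi >= 1 - upper."""
    return 1.0 - da.core_max


def novelty_score(factors: Iterable[float]) -> float:
    """Chain-factorized sequence novelty: the product of per-record factors.

    Factors are the clipped core DAs, ``min(1, max core DA)``, of the flagged
    records; the empty product is 1.
    """
    out = 1.0
    for f in factors:
        out *= float(f)
    return out


@dataclass
class StoredProfile:
    """Reference data accumulated from records classified normal.

    Keeps, per subject, the last accepted normalized feature vector and the
    running mean of accepted records, plus cohort-level means as a global
    fallback for subjects with no accepted record.
    """

    feature_names: tuple[str, ...]
    last_accepted: dict[str, np.ndarray] = field(default_factory=dict)
    running_sum: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def update(self, sid: str, vector: np.ndarray) -> None:
        self.last_accepted[sid] = vector.copy()
        self.running_sum[sid] = self.running_sum.get(sid, 0.0) + vector
        self.counts[sid] = self.counts.get(sid, 0) + 1

    def mean(self, sid: str) -> np.ndarray:
        if sid not in self.counts:
            return self.global_mean()
        return self.running_sum[sid] / self.counts[sid]

    def global_mean(self) -> np.ndarray:
        total = sum(self.counts.values())
        if total == 0:
            raise ValueError("stored profile is empty")
        return sum(self.running_sum.values()) / total


@dataclass
class RecordAssessment:
    """Per-record outcome of the partition sweep."""

    subject_id: str
    index: int
    label: str  # "normal" | "unknown"
    max_core_da: float  # NaN for a subject's first record
    phi: float  # NaN for a subject's first record
    augmentation: bool


@dataclass
class PartitionResult:
    """Outcome of a cohort partition.

    ``Q`` (unknown) and ``V`` (normal) are disjoint sets of
    ``(subject_id, record_index)`` pairs whose union is every record that has
    a predecessor; each subject's first record seeds the stored profile and
    belongs to neither set.
    """

    assessments: list[RecordAssessment]
    Q: set[tuple[str, int]]
    V: set[tuple[str, int]]

    @property
    def unknown_fraction(self) -> float:
        total = len(self.Q) + len(self.V)
        return len(self.Q) / total if total else 0.0

    def novelty_factors(self, subject_id: str) -> list[float]:
        return [
            min(1.0, a.max_core_da)
            for a in self.assessments
            if a.subject_id == subject_id and a.label == "unknown"
        ]

    def subject_novelty(self, subject_id: str) -> float:
        return novelty_score(self.novelty_factors(subject_id))

    def labels(self, subject_id: str) -> np.ndarray:
        """0/1 unknown labels for one subject, in record order (first record 0)."""
        rows = [a for a in self.assessments if a.subject_id == subject_id]
        rows.sort(key=lambda a: a.index)
        return np.array([1 if a.label == "unknown" else 0 for a in rows], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": a.subject_id,
                    "record_index": a.index,
                    "label": a.label,
                    "max_core_DA": a.max_core_da,
                    "phi": a.phi,
                    "augmentation_flag": a.augmentation,
                }
                for a in self.assessments
            ]
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def partition_cohort(
    sequences: Sequence[PatientSequence],
    lower: float = 0.4,
    upper: float = 0.6,
    core_features: Sequence[str] = DEFAULT_CORE_FEATURES,
    feature_names: Sequence[str] | None = None,
) -> tuple[PartitionResult, StoredProfile]:
    """Sweep a normalized cohort in time order and partition it into Q and V.

    Each subject's first record has no predecessor: it is accepted as normal
    by convention, seeds the stored profile, and belongs to neither set.
    Normal records update the stored profile; unknown records do not.
    """
    if not sequences or not any(len(s) for s in sequences):
        raise ValueError("cannot partition an empty cohort")
    if feature_names is None:
        first = next(s for s in sequences if len(s))
        feature_names = tuple(first.records[0].features)
    profile = StoredProfile(tuple(feature_names))
    assessments: list[RecordAssessment] = []
    Q: set[tuple[str, int]] = set()
    V: set[tuple[str, int]] = set()

    for seq in sequences:
        for idx, rec in enumerate(seq.records):
            vec = np.array([rec.features[n] for n in feature_names], dtype=float)
            if idx == 0:
                profile.update(seq.subject_id, vec)
                assessments.append(
                    RecordAssessment(seq.subject_id, idx, "normal", np.nan, np.nan, False)
                )
                continue
            da = compute_da(seq.records[idx - 1], rec, core_features)
            label, augment = classify_record(da, lower, upper)
            phi = similarity(da)
            key = (seq.subject_id, idx)
            if label == "unknown":
                Q.add(key)
            else:
                V.add(key)
                profile.update(seq.subject_id, vec)
            assessments.append(
                RecordAssessment(seq.subject_id, idx, label, da.core_max, phi, augment)
            )
    return PartitionResult(assessments, Q, V), profile


class DifferencePartitioner(BaseEstimator):
    """Estimator wrapper around :func:`partition_cohort`.

    Parameters
    ----------
    lower, upper : float
        The expected-fluctuation band of the core DA; records whose core DA
        exceeds ``upper`` are unknown.
    core_features : tuple of str
        Features whose DA drives the decision.
    """

    def __init__(
        self,
        lower: float = 0.4,
        upper: float = 0.6,
        core_features: Sequence[str] = DEFAULT_CORE_FEATURES,
    ):
        self.lower = lower
        self.upper = upper
        self.core_features = tuple(core_features)

    def fit(self, sequences: Sequence[PatientSequence], y=None) -> "DifferencePartitioner":
        self.partition_, self.profile_ = partition_cohort(
            sequences, self.lower, self.upper, self.core_features
        )
        return self

    def fit_partition(self, sequences: Sequence[PatientSequence]) -> PartitionResult:
        return self.fit(sequences).partition_

    def predict(self, sequences: Sequence[PatientSequence]) -> np.ndarray:
        """0/1 unknown flags for every record of every sequence, in order."""
        partition, _ = partition_cohort(
            sequences, self.lower, self.upper, self.core_features
        )
        return np.concatenate([partition.labels(s.subject_id) for s in sequences])
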