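"""End-to-end orchestration: simulate -> scale -> partition -> learn -> report.

Shared by the command-line interface and the reproduction script so that an
"evaluate" run always means the same computation: fit the min-max scaler on
reference (truth-normal, stable-subject) records, partition the normalized
cohort by difference amplitude, train the recurrent learner on a
subject-level training split, and score the held-out subjects.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CohortMinMaxScaler, PatientSequence
from .config import RunConfig
from .learner import RecurrentVarianceClassifier
from .metrics import MetricsBundle, confusion_metrics
from .pattern import DifferencePartitioner, PartitionResult
from .progression import ProgressionDetector, ProgressionReport
from .simulate import GroundTruth, simulate_cohort

__all__ = ["PipelineResult", "reference_sequences", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything an evaluate run produces."""

    metrics: MetricsBundle
    partition: PartitionResult
    reports: list[ProgressionReport]
    progression_accuracy: float
    classifier: RecurrentVarianceClassifier
    scaler: CohortMinMaxScaler
    train_subjects: list[str]
    test_subjects: list[str]


def reference_sequences(
    sequences: Sequence[PatientSequence], truth: GroundTruth
) -> list[PatientSequence]:
    """Truth-normal records of stable subjects — the scaler's reference data."""
    refs = []
    for seq in sequences:
        if truth.subject_labels[seq.subject_id] != "stable":
            continue
        labels = truth.record_labels[seq.subject_id]
        normal = [rec.copy() for rec, lab in zip(seq.records, labels) if lab == 0]
        if normal:
            refs.append(PatientSequence(seq.subject_id, normal))
    if not refs:
        raise ValueError("no stable truth-normal records to fit the scaler on")
    return refs


def run_pipeline(
    config: RunConfig,
    seed: int | None = None,
    sequences: Sequence[PatientSequence] | None = None,
    truth: GroundTruth | None = None,
) -> PipelineResult:
    """Run the full method on a simulated (or supplied) labeled cohort."""
    config.validate()
    seed = config.seed if seed is None else seed
    if sequences is None:
        sequences, truth = simulate_cohort(config.cohort, seed=seed)
    if truth is None:
        raise ValueError("ground truth required to evaluate the pipeline")

    scaler = CohortMinMaxScaler().fit(reference_sequences(sequences, truth))
    normalized = scaler.transform(sequences)

    partitioner = DifferencePartitioner(
        lower=config.partition.lower,
        upper=config.partition.upper,
        core_features=config.partition.core_features,
    )
    partition = partitioner.fit_partition(normalized)

    # subject-level split, seeded
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(normalized))
    n_test = max(1, int(round(config.test_fraction * len(normalized))))
    test_idx = set(order[:n_test].tolist())
    train_seqs = [normalized[i] for i in range(len(normalized)) if i not in test_idx]
    test_seqs = [normalized[i] for i in sorted(test_idx)]

    feats = list(config.learner.features)
    clf = RecurrentVarianceClassifier(
        hidden_size=config.learner.hidden_size,
        epochs=config.learner.epochs,
        learning_rate=config.learner.learning_rate,
        momentum=config.learner.momentum,
        sq_decay=config.learner.sq_decay,
        damping=config.learner.damping,
        gamma_init=config.learner.gamma_init,
        loss=config.learner.loss,
        threshold=config.learner.threshold,
        random_state=seed,
    )
    clf.fit(
        [s.feature_matrix(feats) for s in train_seqs],
        [truth.record_labels[s.subject_id] for s in train_seqs],
    )

    t0 = time.perf_counter()
    predicted = clf.predict([s.feature_matrix(feats) for s in test_seqs])
    verification_time = time.perf_counter() - t0

    pred_flat = np.concatenate(predicted)
    truth_flat = np.concatenate([truth.record_labels[s.subject_id] for s in test_seqs])

    detector = ProgressionDetector(
        threshold=config.progression.threshold,
        feature=config.progression.feature,
        mode=config.progression.mode,
        aggregate=config.progression.aggregate,
    )
    reports = detector.report(normalized, partition=partition)
    variances = np.concatenate(
        [np.abs(r.series.values) for r in reports if len(r.series.values)]
    )
    metrics = confusion_metrics(
        pred_flat, truth_flat, variances=variances, verification_time=verification_time
    )

    prog_pred = np.array([1 if r.decision == "progressive" else 0 for r in reports])
    prog_truth = np.array(
        [
            1 if truth.subject_labels[s.subject_id] == "progressive" else 0
            for s in normalized
        ]
    )
    progression_accuracy = float(np.mean(prog_pred == prog_truth))

    return PipelineResult(
        metrics=metrics,
        partition=partition,
        reports=reports,
        progression_accuracy=progression_accuracy,
        classifier=clf,
        scaler=scaler,
        train_subjects=[s.subject_id for s in train_seqs],
        test_subjects=[s.subject_id for s in test_seqs],
    )
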