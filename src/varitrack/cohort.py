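"""Cohort data model, CSV dialects and min-max normalization.

Longitudinal voice-telemonitoring data arrive as one CSV row per sensing
instance: a subject identifier, demographics, the time of the test (days since
enrollment) and a set of precomputed voice measures (jitter and shimmer
variants, NHR/HNR, RPDE, DFA, PPE) together with clinician-style UPDRS
severity scores.  Two header dialects are supported:

``uci22``
    the 22-column public telemonitoring layout (``subject#``, ``age``,
    ``sex``, ``test_time`` and 18 measures);
``reduced16``
    a 16-column layout (``subject_id``, ``age``, ``sex``, ``test_time`` and a
    12-measure subset) for exports that record only the personal and medical
    fields.

Downstream difference-amplitude thresholds (0.4/0.6) and the progression
threshold (0.06) are only meaningful on a common bounded scale, so the module
also provides :class:`CohortMinMaxScaler`, a per-feature min-max transformer
fitted on reference (normal) data.  Values scaled outside the training range
are deliberately *not* clipped: an abnormal excursion beyond the reference
range is exactly the signal the thresholds exist to catch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

__all__ = [
    "UCI22_FEATURES",
    "REDUCED16_FEATURES",
    "DIALECTS",
    "DialectError",
    "CohortParseError",
    "ObservationRecord",
    "PatientSequence",
    "CohortMinMaxScaler",
    "read_cohort",
    "write_cohort",
    "fit_scaler",
    "apply_scaler",
    "sequences_to_matrix",
]

#: The 18 measure columns of the public telemonitoring layout, in file order.
UCI22_FEATURES: tuple[str, ...] = (
    "motor_UPDRS",
    "total_UPDRS",
    "Jitter(%)",
    "Jitter(Abs)",
    "Jitter:RAP",
    "Jitter:PPQ5",
    "Jitter:DDP",
    "Shimmer",
    "Shimmer(dB)",
    "Shimmer:APQ3",
    "Shimmer:APQ5",
    "Shimmer:APQ11",
    "Shimmer:DDA",
    "NHR",
    "HNR",
    "RPDE",
    "DFA",
    "PPE",
)

#: The 12-measure subset used by the 16-column dialect.
REDUCED16_FEATURES: tuple[str, ...] = (
    "motor_UPDRS",
    "total_UPDRS",
    "Jitter(%)",
    "Jitter(Abs)",
    "Jitter:RAP",
    "Shimmer",
    "Shimmer(dB)",
    "NHR",
    "HNR",
    "RPDE",
    "DFA",
    "PPE",
)

DIALECTS: dict[str, dict] = {
    "uci22": {"id_column": "subject#", "features": UCI22_FEATURES},
    "reduced16": {"id_column": "subject_id", "features": REDUCED16_FEATURES},
}


class DialectError(ValueError):
    """Header does not match the requested CSV dialect."""


class CohortParseError(ValueError):
    """A cell could not be parsed as a number."""


def dialect_header(dialect: str) -> list[str]:
    """Return the exact expected header tokens for ``dialect``."""
    try:
        spec = DIALECTS[dialect]
    except KeyError:
        raise DialectError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}"
        ) from None
    return [spec["id_column"], "age", "sex", "test_time", *spec["features"]]


@dataclass
class ObservationRecord:
    """One sensing instance for one subject.

    Parameters
    ----------
    subject_id
        Subject identifier (kept as a string).
    test_time
        Days since enrollment; may be non-integer.
    age
        Age in years.
    sex
        Coded 0/1.
    features
        Named map feature name -> real value.
    """

    subject_id: str
    test_time: float
    age: int
    sex: int
    features: dict[str, float] = field(default_factory=dict)

    def validate(self, feature_names: Iterable[str]) -> None:
        """Raise ``ValueError`` unless every configured feature is present and finite."""
        if not math.isfinite(self.test_time):
            raise ValueError(f"non-finite test_time for subject {self.subject_id}")
        for name in feature_names:
            if name not in self.features:
                raise ValueError(
                    f"record for subject {self.subject_id} is missing feature {name!r}"
                )
            if not math.isfinite(self.features[name]):
                raise ValueError(
                    f"non-finite value for feature {name!r} of subject {self.subject_id}"
                )

    def copy(self) -> "ObservationRecord":
        return ObservationRecord(
            self.subject_id, self.test_time, self.age, self.sex, dict(self.features)
        )


@dataclass
class PatientSequence:
    """Time-ordered observation records of a single subject.

    Records are sorted by nondecreasing ``test_time``; ties keep input order.
    """

    subject_id: str
    records: list[ObservationRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.subject_id != self.subject_id:
                raise ValueError(
                    f"record subject {rec.subject_id!r} != sequence subject {self.subject_id!r}"
                )
        times = [rec.test_time for rec in self.records]
        if any(b < a for a, b in zip(times, times[1:])):
            # stable sort: ties keep input order
            order = np.argsort(np.asarray(times), kind="stable")
            self.records = [self.records[i] for i in order]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([rec.test_time for rec in self.records], dtype=float)

    def feature_matrix(self, feature_names: Sequence[str]) -> np.ndarray:
        """Stack the named features into a ``(n_records, n_features)`` array."""
        return np.array(
            [[rec.features[name] for name in feature_names] for rec in self.records],
            dtype=float,
        )

    def copy(self) -> "PatientSequence":
        return PatientSequence(self.subject_id, [rec.copy() for rec in self.records])


def read_cohort(path: str | Path, dialect: str = "uci22") -> list[PatientSequence]:
    """Read a telemonitoring-style CSV into one :class:`PatientSequence` per subject.

    The header must match ``dialect`` exactly.  Records come back sorted by
    ``test_time`` within each subject (stable for ties); the total record
    count equals the number of data rows in the file.

    Raises
    ------
    DialectError
        Missing or extra columns (named in the message).
    CohortParseError
        A non-numeric cell, with its row number (1-based, counting the header).
    """
    expected = dialect_header(dialect)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    got = list(df.columns)
    if got != expected:
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        detail = []
        if missing:
            detail.append(f"missing columns {missing}")
        if extra:
            detail.append(f"extra columns {extra}")
        if not detail:
            detail.append(f"column order {got} != expected {expected}")
        raise DialectError(f"header does not match dialect {dialect!r}: " + "; ".join(detail))

    numeric = {}
    for col in expected[1:]:  # identifier column stays textual
        raw = df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            cell = raw.iloc[i]
            raise CohortParseError(
                f"non-numeric cell {cell!r} in column {col!r} at row {i + 2}"
            )
        numeric[col] = vals.to_numpy(dtype=float)

    id_col = expected[0]
    features = DIALECTS[dialect]["features"]
    subject_ids = df[id_col].astype(str).str.strip().to_numpy()
    sequences: dict[str, list[ObservationRecord]] = {}
    for i in range(len(df)):
        sid = subject_ids[i]
        rec = ObservationRecord(
            subject_id=sid,
            test_time=float(numeric["test_time"][i]),
            age=int(numeric["age"][i]),
            sex=int(numeric["sex"][i]),
            features={name: float(numeric[name][i]) for name in features},
        )
        sequences.setdefault(sid, []).append(rec)
    return [PatientSequence(sid, recs) for sid, recs in sequences.items()]


def write_cohort(
    sequences: Sequence[PatientSequence], path: str | Path, dialect: str = "uci22"
) -> None:
    """Write sequences as a CSV readable by :func:`read_cohort`.

    Numeric fields are serialized with 12 significant digits so a
    read-after-write round trip preserves values to better than 1e-9 relative.
    Records are validated (full feature set, finite values) before anything is
    written.
    """
    if not sequences:
        raise ValueError("cannot write an empty cohort")
    features = DIALECTS[dialect]["features"]
    for seq in sequences:
        for rec in seq.records:
            rec.validate(features)

    header = dialect_header(dialect)
    rows = []
    for seq in sequences:
        for rec in seq.records:
            row = [
                rec.subject_id,
                str(rec.age),
                str(rec.sex),
                format(rec.test_time, ".12g"),
            ]
            row.extend(format(rec.features[name], ".12g") for name in features)
            rows.append(row)
    out = pd.DataFrame(rows, columns=header)
    out.to_csv(path, index=False)


def sequences_to_matrix(
    sequences: Iterable[PatientSequence], feature_names: Sequence[str]
) -> np.ndarray:
    """Stack every record of every sequence into one ``(n_records, n_features)`` array."""
    mats = [seq.feature_matrix(feature_names) for seq in sequences]
    if not mats:
        raise ValueError("empty cohort")
    return np.vstack(mats)


class CohortMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-feature min-max scaler operating on :class:`PatientSequence` lists.

    Fitted on reference (normal) data, it maps each training value into
    ``[0, 1]`` via ``v' = (v - min) / (max - min)``.  Constant features map to
    0.  Values transformed after fitting may fall outside ``[0, 1]`` and are
    *not* clipped — out-of-range excursions carry the abnormality signal.

    Parameters
    ----------
    feature_names : sequence of str, optional
        Features to scale.  Defaults to every feature of the first record
        seen at fit time, in that record's order.

    Attributes
    ----------
    feature_names_ : tuple of str
    min_, max_ : ndarray of shape (n_features,)
    """

    def __init__(self, feature_names: Sequence[str] | None = None):
        self.feature_names = feature_names

    def fit(self, sequences: Sequence[PatientSequence], y=None) -> "CohortMinMaxScaler":
        if not sequences or not any(len(s) for s in sequences):
            raise ValueError("cannot fit a scaler on an empty cohort")
        if self.feature_names is not None:
            names = tuple(self.feature_names)
        else:
            first = next(s for s in sequences if len(s))
            names = tuple(first.records[0].features)
        mat = sequences_to_matrix([s for s in sequences if len(s)], names)
        if not np.all(np.isfinite(mat)):
            raise ValueError("non-finite feature values in training cohort")
        self.feature_names_ = names
        self.min_ = mat.min(axis=0)
        self.max_ = mat.max(axis=0)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "min_"):
            raise NotFittedError(
                "this CohortMinMaxScaler instance is not fitted yet; call fit first"
            )

    def transform_matrix(self, mat: np.ndarray) -> np.ndarray:
        """Scale a raw ``(n, n_features)`` array (feature order = ``feature_names_``)."""
        self._check_fitted()
        rng = self.max_ - self.min_
        safe = np.where(rng > 0, rng, 1.0)
        out = (np.asarray(mat, dtype=float) - self.min_) / safe
        return np.where(rng > 0, out, 0.0)

    def inverse_transform_matrix(self, mat: np.ndarray) -> np.ndarray:
        self._check_fitted()
        rng = self.max_ - self.min_
        return np.asarray(mat, dtype=float) * rng + self.min_

    def _map(self, sequences, fn) -> list[PatientSequence]:
        self._check_fitted()
        out = []
        for seq in sequences:
            new = seq.copy()
            if len(new):
                scaled = fn(new.feature_matrix(self.feature_names_))
                for rec, row in zip(new.records, scaled):
                    for j, name in enumerate(self.feature_names_):
                        rec.features[name] = float(row[j])
            out.append(new)
        return out

    def transform(self, sequences: Sequence[PatientSequence]) -> list[PatientSequence]:
        return self._map(sequences, self.transform_matrix)

    def inverse_transform(self, sequences: Sequence[PatientSequence]) -> list[PatientSequence]:
        return self._map(sequences, self.inverse_transform_matrix)

    def to_json(self) -> dict:
        self._check_fitted()
        return {
            "method": "min-max",
            "features": {
                name: {"min": float(lo), "max": float(hi)}
                for name, lo, hi in zip(self.feature_names_, self.min_, self.max_)
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @classmethod
    def from_json(cls, payload: Mapping) -> "CohortMinMaxScaler":
        feats = payload["features"]
        obj = cls(feature_names=tuple(feats))
        obj.feature_names_ = tuple(feats)
        obj.min_ = np.array([feats[n]["min"] for n in feats], dtype=float)
        obj.max_ = np.array([feats[n]["max"] for n in feats], dtype=float)
        return obj

    @classmethod
    def load(cls, path: str | Path) -> "CohortMinMaxScaler":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_scaler(
    sequences: Sequence[PatientSequence], feature_names: Sequence[str] | None = None
) -> CohortMinMaxScaler:
    """Fit a :class:`CohortMinMaxScaler` on a (reference) cohort."""
    return CohortMinMaxScaler(feature_names=feature_names).fit(sequences)


def apply_scaler(
    scaler: CohortMinMaxScaler, sequences: Sequence[PatientSequence]
) -> list[PatientSequence]:
    """Return normalized copies of ``sequences`` (original cohort untouched)."""
    return scaler.transform(sequences)
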