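import numpy as np
import pytest

from varitrack.cohort import ObservationRecord, PatientSequence


def make_record(sid, t, feats, age=65, sex=0):
    return ObservationRecord(subject_id=sid, test_time=float(t), age=age, sex=sex,
                             features=dict(feats))


@pytest.fixture
def toy_features():
    """A small feature map with the fields the pipeline consults by default."""
    return {
        "motor_UPDRS": 0.5,
        "total_UPDRS": 0.5,
        "Jitter(%)": 0.5,
        "Jitter(Abs)": 0.5,
        "Jitter:RAP": 0.5,
        "Shimmer": 0.5,
        "Shimmer(dB)": 0.5,
        "NHR": 0.5,
        "HNR": 0.5,
        "RPDE": 0.5,
        "DFA": 0.5,
        "PPE": 0.5,
    }


@pytest.fixture
def toy_sequence(toy_features):
    """Four normalized records of one subject with controlled core-feature jumps.

    Successive core DAs are 0.00, 0.45 and 0.61: two normal steps (one inside
    the expected 0.4-0.6 band) and one excursion beyond the band.
    """
    jitter = [0.10, 0.10, 0.55, 0.55]
    shimmer = [0.20, 0.20, 0.20, 0.81]
    records = []
    for k in range(4):
        feats = dict(toy_features)
        feats["Jitter(%)"] = jitter[k]
        feats["Shimmer"] = shimmer[k]
        records.append(make_record("T1", k, feats))
    return PatientSequence("T1", records)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
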