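# varitrack

Variance-based pattern recognition and progression tracking for longitudinal
telemonitoring cohorts.

`varitrack` is aimed at researchers who monitor neurodegenerative-disease
patients through frequent at-home sensing — the canonical setting is
Parkinson's voice telemonitoring, where ~42 subjects are each observed through
120–148 sensing instances carrying UPDRS severity scores and voice measures
(jitter and shimmer variants, NHR/HNR, RPDE, DFA, PPE).  The package answers
three questions about such a cohort:

1. **Which records are *unknown*?**  On the min–max-normalized [0, 1] scale,
   the *difference amplitude* of a core feature between successive records,
   `DA_f(α) = |x̃_f(α) − x̃_f(α−1)|`, is expected to fluctuate inside the band
   [0.4, 0.6].  A record with `max_core DA > 0.6` does not match the stored
   patient data: it is assigned to the unknown set *Q*, its similarity
   `φ = 1 − max core DA` drops below 0.4, and an augmentation flag demands the
   additional NHR/RPDE/DFA observations at the next sensing instance.
   Everything else joins the normal set *V*, which updates the stored profile
   and feeds training.

2. **Which records are *abnormal*?**  A from-scratch gated recurrent cell
   (input/forget/output gates, internal cell state, logistic gate
   nonlinearity θ) is unrolled over each normalized sequence.  Its hidden
   state passes through a *variance activation* with a learned per-unit leak
   γ,

       F(a) = a       if a > 0
       F(a) = γ·a     if a ≤ 0,

   and the per-record abnormality score is `θ(u·F(a_α) + b)`.  All gradients
   — including ∂R/∂γ (zero on the positive branch, the pre-activation itself
   on the negative branch) and the readout gradient ∂R/∂U — are derived
   analytically and verified against finite differences.  Updates use
   heavy-ball momentum with an adaptive damping ratio `J/(c + J)`, where `J`
   is an exponential average of squared gradients.

3. **Which subjects are *progressing*?**  Per subject, the variance series of
   the designated progression feature (default `Jitter:RAP`) — successive
   absolute normalized differences, or model-score deviations from the stored
   reference — is aggregated to `Z = max(series)`; the subject is flagged
   progressive iff `Z > 0.06` (strict).  A cohort-level retraining trigger
   fires when the unknown fraction `|Q| / (|Q| + |V|)` exceeds a configurable
   threshold.

A seeded synthetic-cohort generator with ground-truth normal/abnormal and
progressive/stable labels makes every stage testable end to end.

## Worked example

```python
import numpy as np
import varitrack as vt

# a labeled synthetic cohort: 10 subjects, half with an abnormal step shift
cfg = vt.CohortConfig(n_subjects=10, seq_len_range=(40, 40), seed=1)
sequences, truth = vt.simulate_cohort(cfg)

# normalize on reference (stable, truth-normal) data
from varitrack.pipeline import reference_sequences
scaler = vt.fit_scaler(reference_sequences(sequences, truth))
normalized = scaler.transform(sequences)

# difference-amplitude partition
part, profile = vt.partition_cohort(normalized)
print(len(part.Q), len(part.V), round(part.unknown_fraction, 4))
# -> 5 385 0.0128

# train the recurrent learner on truth labels and score the records
feats = ["Jitter(%)", "Shimmer", "NHR", "RPDE", "DFA"]
clf = vt.RecurrentVarianceClassifier(random_state=1).fit(
    [s.feature_matrix(feats) for s in normalized],
    [truth.record_labels[s.subject_id] for s in normalized],
)
pred = np.concatenate(clf.predict([s.feature_matrix(feats) for s in normalized]))
m = vt.confusion_metrics(pred, np.concatenate(
    [truth.record_labels[s.subject_id] for s in normalized]))
print(round(m.accuracy, 3), round(m.precision, 3), m.pattern_verification)
# -> 1.0 1.0 96

# per-subject progression reports
for r in vt.progression_report_cohort(normalized)[:3]:
    print(r.subject_id, round(r.score, 4), r.decision)
# -> S01 0.2276 progressive
# -> S02 0.2247 progressive
# -> S03 0.042 stable
```

The partition flags the 5 injected step onsets among 390 eligible records
(unknown fraction 1.3%); the trained learner classifies every record correctly and confirms all 96
abnormal records (precision 1.0); and the maximum per-step `Jitter:RAP`
variance separates ramped subjects (`Z ≈ 0.23 > 0.06`) from stable ones
(`Z ≈ 0.04`).

A command-line interface mirrors the library:

```sh
varitrack simulate --seed 7 --out-dir run/
varitrack partition --cohort run/cohort.csv --truth run/truth.csv --out run/partition.csv
varitrack train    --cohort run/cohort.csv --truth run/truth.csv --model-out run/model.json
varitrack progress --cohort run/cohort.csv --truth run/truth.csv --out run/progress.jsonl
varitrack evaluate --seed 7 --out run/metrics.json
```

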