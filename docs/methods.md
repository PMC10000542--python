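# Methods

## Setting and data model

`varitrack` operates on longitudinal telemonitoring cohorts: each subject
contributes an ordered sequence of observation records (days since
enrollment, demographics, and a set of precomputed voice and severity
measures).  Two CSV dialects are supported — the 22-column public
telemonitoring layout (`uci22`) and a 16-column reduced layout
(`reduced16`) — because study descriptions of such cohorts variously count
16 personal-and-medical fields or the full 22-column file.  Both are offered
rather than guessing which subset a given export contains; `uci22` is the
default.  Within a subject, records are sorted by nondecreasing test time
with ties broken by file order, so sequences are deterministic.

All thresholds of the method (the 0.4–0.6 difference-amplitude band, the
0.06 progression threshold) are only meaningful on a common bounded scale.
Features are therefore min–max normalized, with the scaler fitted on
*reference* (normal) data only.  Values outside the training range are not
clipped: an abnormal excursion beyond the reference range is precisely the
signal the thresholds exist to catch.  Constant features map to 0.  The
0.06 progression threshold is applied on normalized units for the same
scale-consistency reason; raw-unit operation would make the threshold depend
on the measure's physical range.

## Pattern stage: difference-amplitude partition

For every record with a predecessor, the difference amplitude
`DA_f = |x̃_f(α) − x̃_f(α−1)|` is computed per normalized feature.  The core
set defaults to {Jitter(%), Shimmer} — the two measures the decision rule is
stated for — and is configurable.  The decision is:

* `max core DA > 0.6` → **unknown** (set Q), augmentation flag raised: the
  additional NHR/RPDE/DFA observations are required at the next sensing
  instance.  In fully featured data these columns already exist, so the flag
  gates which features downstream consumers consult rather than triggering a
  new measurement.
* otherwise → **normal** (set V).  The band [0.4, 0.6] is the expected
  fluctuation range of the core DA; values inside and below it are treated
  identically because no operational distinction between them is defined.

Each subject's first record has no predecessor; it is accepted as normal by
convention, seeds the stored profile, and belongs to neither Q nor V.  The
stored profile keeps the last accepted normalized vector and the running
mean of accepted records per subject (plus cohort means as a global
fallback); the running mean serves as the reference vector for model-mode
variance.  DA for classification is computed against the immediately
previous record — the literal "between two successive sequences" reading —
not against the stored reference; consequently a persistent level shift is
flagged at its onset record, and post-onset records (shifted vs. shifted)
are normal again.  Detecting the persistence of the shift is the learner's
job.

The record similarity is `φ = 1 − max core DA ∈ (−∞, 1]`, so "normal" is
equivalent to `φ ≥ 0.4`.  A sequence-level novelty score — the product of
`min(1, max core DA)` over flagged records, empty product 1 — is logged for
inspection only.  A recurrent encoder `A_0 = 0`,
`A_α = logistic(W x_α + S A_{α−1})` is provided as the sequence-encoding
primitive; the logistic function is used as the (otherwise unspecified)
squashing map, matching the gate nonlinearity of the learner so one
convention covers the whole method.

## Recurrent variance learner

The cell is a standard gated recurrent unit with input gate i, forget gate
d, output gate b and internal cell state c (see the `learner` module
docstring for the equations).  Two completions were needed to make the cell
well posed: the input-gate and candidate equations are written symmetrically
to the stated forget/output gates, and each affine gate carries a bias
vector (initialized at 0).  The output gate peeks at the *current* cell
state, which is the stated form; backpropagation handles the extra edge.

The hidden state feeds a **variance activation**: a parametric leaky
rectifier `F(a) = a` for `a > 0`, `γ·a` for `a ≤ 0`, with a learned per-unit
leak γ.  The equivalent rectifier-sum form
`G(a) = max(0, a) + γ·min(0, a)` is implemented separately and asserted
pointwise identical — the two-layer reading of the analysis stage (one layer
for the variance value, one for the leak estimation) collapses to a single
function, and the test suite pins that equivalence.  The abnormality score
of a record is `θ(u·F(a_α) + bias)`.

Training minimizes mean squared error over all (valid) records
(cross-entropy available behind a switch); MSE is the simplest
differentiable choice for the unspecified objective R.  All gradients are
derived by hand and backpropagated through time.  Two are notable:

* `∂R/∂γ_i = Σ upstream · I(a_i)` with `I(a) = a` on the nonpositive branch
  and 0 otherwise;
* the readout gradient `∂R/∂u = Σ dlogit · F(a)`.

Gradient-oracle equivalence (central finite differences, h = 1e-6, relative
tolerance 1e-5 with an absolute floor of 1e-8 — the oracle's own roundoff
floor, |R|·ε/h ≈ 1e-11) is the central correctness criterion for this
module, checked per parameter block on seeded 2-unit/3-step/2-record
instances.

**Optimizer.**  Updates are heavy-ball momentum with an adaptive damping
ratio, per parameter block:

    m ← λ_m·m + lr·g        (momentum accumulator)
    J ← β·J + (1−β)·g²      (squared-gradient average, J ≥ 0)
    Z = c + J               (damping-adjusted scale, Z > 0)
    p ← p − m·J/Z

Defaults: λ_m = 0.9, β = 0.9, lr = 0.5, c = 1e-6, hidden size 8, γ
initialized at 0.25 (the canonical parametric-leak default), weights
~ U(−0.1, 0.1) under the run seed.  The damping constant c was originally
envisaged at 1e-2, but at that scale J (≈ g² ≈ 1e-6 for this problem class)
sits far below c, the ratio J/Z collapses and training stalls near the
base-rate constant predictor; c = 1e-6 keeps the warm-up damping behaviour
while letting J dominate once gradients are established.  Training is
full-batch (sequences padded and masked), hence bit-deterministic given the
initialization seed; the loss trace is recorded per epoch.

## Progression stage

Per subject, the variance series is either the successive absolute
normalized differences of the designated progression feature (`da` mode,
default) or `|score_α − reference score|` with the reference score computed
on the stored-profile mean (`model` mode).  The designated feature defaults
to `Jitter:RAP` — the only R-named jitter variant, standing in for the
loosely named "Jitter RPP" of the telemonitoring description — and is
configurable.  The subject score is `Z = max(series)` (mean aggregation
optional), and the decision is progressive iff `Z > 0.06` strictly,
following the "exceeding" language of the rule.  Retraining on accumulated
variance is recommended when `|Q|/(|Q|+|V|) > 0.2` (the fraction is
configurable; no canonical value exists).

## Synthetic cohorts

The generator emulates the telemonitoring study structure: default 42
subjects, 120–148 sensing instances at irregular 0.5–3-day intervals,
per-subject feature trajectories

    x_f(t) = baseline_f(s) + slope_f(s)·t + ε,   ε ~ N(0, σ_f),

clamped to plausible physical bounds.  Baseline means, between-subject SDs
and bounds follow published plausible ranges of the telemonitoring measures
(e.g. Jitter(%) 0.0062 ± 0.0020 within [0.0001, 0.12]).  Design choices that
were genuinely open:

* **Sensing noise** σ_f = 0.02 × between-subject SD.  The progression
  threshold (0.06 on normalized successive differences) presupposes that
  normal fluctuation stays below it; with ~40 baselines spanning the
  normalized range, this noise level keeps the maximum normal successive
  difference near 0.02–0.05, comfortably under the threshold, while still
  being visible to the learner.
* **Abnormal events** are step shifts on the core features from a random
  onset (uniform over the middle half of the sequence), default magnitude
  160 × σ_f ≈ 3.2 × between-subject SD — large on the population scale, as
  the DA > 0.6 rule presumes (a one-step excursion spanning more than 0.6 of
  the observed normalized range).  Half the subjects are abnormal by
  default; the fraction is free in the study description.
* **Progression** is a linear per-visit ramp on the progression feature,
  default increment 25 × σ_f per visit, so the per-step normalized variance
  exceeds 0.06 under the default cohort's normalization.  Half the subjects
  are progressive by default (no canonical value exists).
* **Record labels** mark the shifted segment (abnormal from onset); ramped
  subjects carry the subject-level `progressive` label.  Scaler reference
  data are the truth-normal records of stable subjects.

The **detection study** (`detection_study_config`) isolates the learner: 20
subjects × 60 records, between-subject SD set equal to the noise SD
(homogeneous cohort) and a step shift of 4 noise SDs on the core features
for half the subjects.  Homogeneity makes record-level separability a
property of the shift rather than of subject identity; in heterogeneous
cohorts the partition stage, which is explicitly sequential, carries the
subject-specific context.

**What passing tests do not show.**  The generator is linear-Gaussian with
a single step/ramp event per subject: it contains no UPDRS clinical
dynamics, no medication cycles, no missing data, no heteroscedastic
measurement error and no correlation structure between measures.  Synthetic
recovery therefore demonstrates algorithmic correctness of the stages under
their stated semantics, not clinical performance on real voice data.

## Numerical choices and degenerate inputs

* Everything runs in float64; gates are computed with the numerically stable
  logistic of `scipy.special.expit`.
* Padded batch steps carry zero loss gradient and provably contribute
  nothing to any parameter gradient (padding is terminal).
* Constant features scale to 0; an empty cohort, an empty variance series,
  an unfitted scaler or classifier, mismatched shapes and non-finite inputs
  all raise typed errors before any computation.
* Tie-breaks: records with equal test times keep file order; the DA decision
  uses strict inequality at 0.6, as does the progression decision at 0.06
  (band edges are normal/stable).
* Problem sizes in the test suite and the reproduction script (20–42
  subjects, 40–148 records, 200–300 epochs) were chosen so each stage's
  behaviour is measurable with comfortable statistical margins at desk
  scale.

## Known limitations

* The record-level learner is trained supervised on ground-truth labels; the
  one-class fallback (labels from the partition stage) is available but the
  partition's successive-difference labels mark onsets, not persistent
  segments, so the two label sources measure different things.
* Verification time is wall-clock and hardware-dependent; it is reported but
  never asserted.
* The η quantity occasionally mentioned alongside the leak estimation has no
  definition and is not implemented.
* Model-mode variance depends on the stored-profile mean and hence on the
  partition's acceptance decisions; under heavy contamination the reference
  drifts.
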