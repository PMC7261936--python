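# Methods

This note documents the models, parameter choices and numerical decisions
behind `spastiq`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Signal chain

Input trials carry four sEMG channels (μV, 2 kHz) in the fixed order
BB, TB, BR, BA and a 3-axis gyroscope stream (°/s) already interpolated to
the sEMG length (a linear resampler for raw 400 Hz streams is provided).
The hardware stage (amplification, 10–500 Hz analogue filtering) is
assumed to be applied upstream; the software chain applies

| stage | default | note |
|---|---|---|
| sEMG band-pass | 20–350 Hz, 4th-order Butterworth | removes motion artefact/ECG below, noise above |
| sEMG notch | 50 Hz, Q = 30 | mains interference |
| gyro low-pass | 10 Hz, 4th-order Butterworth | angle-band signal only |

All filters run zero-phase (forward–backward). The filter family and
order are not dictated by the problem; Butterworth + zero-phase is the
common sEMG practice, and zero-phase matters here because group delay
would bias the reflex-onset *angle*, the pipeline's most latency-sensitive
quantity.

## Kinematics

The elbow is modelled as a hinge: per-axis cumulative trapezoidal
integrals of the gyro rates are summed (signed superposition) into the
joint angle, extension positive, zero at the flexed start. The resultant
angular velocity is the Euclidean norm of the three rates. Because a
trial returns the arm to its start posture, integration drift is removed
by subtracting the straight line through the trajectory's endpoints; only
the endpoint constraint is assumed (a constant gyro bias is removed
exactly by this correction). The correction is idempotent and leaves
ω unchanged.

## Segment detection

**Patients.** The analysis segment starts at the stretch-reflex sEMG
onset, searched over the three flexor channels (BB, BR, BA — the spastic
muscles in flexor spasticity) with the earliest detection winning, and
ends at the maximal elbow angle (half-open interval, 0-based indices).
The onset detector: envelope = zero-phase 50 Hz low-pass of |x|; baseline
mean/SD from the first 250 ms (the protocol guarantees a quiet lead-in);
onset = start of the first contiguous envelope run above mean + 1.5·SD
that lasts ≥ 100 ms and contains a crossing of mean + 3·SD. Backtracking
to the run start removes the envelope rise-time bias. The 100 ms sustain
criterion is deliberate: at a 50 Hz envelope cutoff the envelope's
correlation time is ~20 ms, so a 25 ms criterion admits chance excursions
of stationary background noise, whereas genuine reflex bursts persist for
hundreds of ms (they last until maximal extension). A burst already in
progress inside the baseline window defeats baseline estimation and
returns the no-onset sentinel — a stated limitation, acceptable because
the protocol starts recording before the stretch.

**Healthy subjects** have no reflex burst inside the biomechanical range,
so their segment starts at the kinematic onset: the first sample with
resultant angular velocity strictly above 7.1 °/s *and* joint angle
strictly above 1.2° (the peak values observed when an elbow is held
statically). Patient trials without a detectable burst fall back to this
rule with a warning.

Windows are 256 samples (128 ms) advancing by 128 samples (64 ms);
partial tails are discarded.

## Features

Per channel and window: RMS; the zero-cross statistic implemented
literally as the fraction of strictly-positive adjacent-sample products
(an affine transform of the conventional crossing rate, which is
available behind a flag — the choice cannot affect any downstream model
that includes an affine layer); waveform length Σ|Δx|; the 4th
coefficient of a Yule-Walker AR(4) fit (the full coefficient vector and
residual variance are retained on the `ARFit` object; the 4th is exported
because the feature set has exactly one AR slot per channel); and mean
power frequency over an unwindowed periodogram of the 256-sample window.
Degenerate windows (constant, zero power) export 0 with a warning. No
MVC or other amplitude normalisation is applied.

## ANFIS

First-order Sugeno system, Gaussian memberships, product firing
strengths, normalisation, linear consequents — the standard five-layer
network. Structure identification is subtractive clustering with
radius 0.65 on inputs min-max scaled to [0, 1] (a radius is only
meaningful on a normalised space), squash factor 1.5, densities
D_i = Σ_j exp(−‖x_i−x_j‖²/(r/2)²). Selection is greedy: densest point,
Gaussian density revision around it (negatives clamped to 0), repeat
until the best remaining density falls below `reject_ratio · D_c1`.

`reject_ratio` defaults to **0.05** rather than the textbook 0.15. On
window clouds from stretch cohorts, one dominant and very compact cluster
— quiet-muscle background windows — sets the reference density D_c1,
while the informative severity clusters are an order of magnitude
sparser (measured at 0.10–0.15 of D_c1 on synthetic cohorts, with noise
centers below 0.03). A cut at 0.15 lands exactly on the informative
clusters: rule counts then flip fold-to-fold and the model frequently
collapses to a single rule, i.e. one global linear map, which
systematically over-predicts healthy subjects and compresses the severe
end. 0.05 accepts the informative clusters with margin on both sides.

Premise widths follow the radius-to-sigma convention
δ_d = radius · range_d / √8; consequents are zero-initialised and fitted
by one global linear least-squares pass over the design matrix
[w̄_i·x, w̄_i] (minimum-norm solution with a warning when rank-deficient).
Least-squares-only training is the default — it is exact in one pass, so
an epoch count is irrelevant; an optional hybrid mode interleaves
numerically-backtracked gradient steps on {c, δ} with fresh LSE passes
and guarantees a non-increasing training residual. The module contains
no randomness; all ties break to the lowest index. Models serialise to
JSON with exact float round-trip.

## Evaluation protocol

MAS labels 0/1/1+/2 digitise to 0/1/1.5/2 (grades 3–4 are out of cohort
and rejected). Cross-validation is leave-one-subject-out; the fold unit
is the subject, and standardisation, PCA (components retained to ≥95 %
cumulative explained variance), clustering and consequent training are
all refitted per fold on training subjects only — an explicit leakage
probe in the test suite verifies that perturbing held-out data leaves
fold models bit-identical. (A `global_pca` switch exists for fidelity
experiments.) A subject's score is the mean prediction over its windows,
clipped to the bounded score space [0, 2]. Reported metrics: R², RMSE,
Pearson r, and unweighted Cohen's κ after rounding to the nearest
digitised level (ties toward the higher level).

The k-trial robustness protocol samples k fast trials per subject without
replacement and re-runs the whole cross-validation, three repeats by
default. Each repeat permutes every subject's trials once and takes the
first k, so subsets are nested across k (common random numbers): the
comparison of protocol sizes is paired, not confounded by independent
resampling noise.

## TSRT baseline

Per patient trial, the dynamic threshold is (peak resultant angular
velocity over the stretch, elbow angle at sEMG onset); a mean-velocity
summary is available behind a flag. Ordinary least squares of angle on
velocity across all three speed classes gives the TSRT as the
zero-velocity intercept; healthy subjects take the biomechanical 140°.
The mapping from TSRT to a MAS-scale score is a within-fold linear
calibration on the training subjects, clipped to [0, 2] — a documented
stand-in for threshold-scoring procedures published elsewhere, not a
reproduction of any of them.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline relies on,
with all planted quantities returned in a truth table.

* **Trajectory**: logistic rise to 140°, short hold, logistic return,
  ≥0.3 s quiet lead-in; peak velocity per class 30/90/180 °/s ± 20 %.
* **Gyro**: the rate split across axes by the fixed direction
  (2/3, 2/3, −1/3) — components sum to 1 and have unit norm, so angle
  superposition and rate norm are both exact. Axis rates invert the
  trapezoid rule so integration is an exact inverse; constant bias
  (U(−0.3, 0.3) °/s per trial) and white noise (SD 0.5 °/s) are added.
* **sEMG**: 20–350 Hz band-limited Gaussian background (σ ≈ 8 μV with
  ±10 % subject jitter). Patient flexor channels add a reflex burst from
  the planted onset angle to maximal extension (10 ms rise ramp), with
  band (80, 160) Hz shifted up by 20/60/100 Hz and amplitude 4/6/8 ×
  background σ for MAS 1/1+/2, scaled by (1 + 0.3·v_peak/100). Onset
  angle per trial is Normal(subject mean − 0.08·v_peak, 3°); subject
  means default to 95/75/55° for MAS 1/1+/2. Per-subject traits jitter
  (gain ×e^N(0,0.1), onset ±4°, band ±8 Hz) so subjects within a grade
  are similar but not identical.
* **Trial-to-trial variability**: burst gain is multiplied by
  e^N(0, 0.3) per trial (~30 % coefficient of variation, typical of
  reflex-burst amplitudes across repeated stretches). This is the
  mechanism that makes single-trial assessments materially less accurate
  than 4-trial averages — the robustness profile the multi-trial protocol
  exists to address.
* **Composition**: 15 subjects (4 healthy, 3/5/3 at MAS 1/1+/2), 18
  trials each (6 per speed class). Everything derives deterministically
  from the master seed via `SeedSequence([seed, subject, trial])`;
  regeneration is byte-identical.

These constants are package defaults chosen to make severity levels
separable but overlapping; they carry no claim of physiological
calibration. What passing tests show: the pipeline recovers planted
structure (onset angles within ±2°, grades with R² ≥ 0.9) under realistic
noise. What they do not show: performance on real patients — real sEMG
has non-Gaussian, non-stationary bursts, electrode and crosstalk
artefacts, and therapist-dependent stretch profiles none of which are
modelled. The generator's DSRT structure is exactly linear in velocity by
construction, so the synthetic TSRT baseline is flattered (R² ≈ 0.99)
relative to what degraded threshold estimates produce clinically; its
value here is as a structural check (negative slopes, severity ordering),
not a performance comparison.

## Numerical choices and edge cases

* Half-open [start, end) segments; windows never cross the maximal-angle
  sample; segments shorter than one window yield zero windows + warning.
* `argmax`-style ties everywhere resolve to the earliest index.
* Gaussian firing strengths are evaluated in log space and shifted by the
  row maximum before normalisation, so predictions remain defined far
  from all rule centers where raw strengths underflow.
* Constant feature columns fall back to unit scale (with a warning) in
  standardisation; constant windows export zero features.
* Angle thresholds (7.1 °/s, 1.2°) are strict inequalities; predictions
  are clipped at the subject level.
* All study constants live in the config dataclasses (`RunConfig` and the
  module configs it composes), never inline in pipeline logic; YAML
  overrides are validated and unknown keys rejected.

## Problem sizes

The default experiment sizes — 15 subjects, 18 trials each, 2 kHz, the
4-trial protocol with 3 repeats — are the package's standard operating
point; the full acceptance recomputation runs in well under a minute on a
single CPU, and the test suite in about a minute and a half.
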