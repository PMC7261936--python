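# spastiq

Quantitative spasticity scoring from surface-EMG and gyroscope recordings
of passive elbow-stretch trials.

## The problem

Post-stroke spasticity — a velocity-dependent increase in muscle resistance
to passive stretch — is usually graded with the Modified Ashworth Scale
(MAS), an ordinal clinical score (0, 1, 1+, 2, 3, 4) that depends heavily
on the therapist's subjective impression. The established objective
alternative, the tonic stretch-reflex threshold (TSRT), needs dozens of
carefully controlled stretches per patient. `spastiq` implements a
regression pipeline that maps a handful of fast passive stretches —
four surface-EMG channels over the elbow muscles (biceps brachii, triceps
brachii, brachioradialis, brachialis) at 2 kHz plus a 3-axis gyroscope on
the brachioradialis sensor — onto a continuous MAS-scale score, together
with the classical TSRT baseline for comparison.

Because clinical stretch-trial datasets of this kind are not publicly
distributable, the package ships a synthetic cohort generator that plants
known ground truth (onset angles, burst gains, spectral shifts, severity
grades), so every stage of the pipeline is testable end to end.

## The method

Per trial: sEMG is band-pass filtered 20–350 Hz with a 50 Hz notch; the
gyroscope is low-pass filtered at 10 Hz, integrated per axis and summed
into the elbow angle θ(t) (endpoint-consistency detrended). The analysis
segment runs from the stretch-reflex sEMG onset (patients; envelope
double-threshold detector) or the kinematic onset (ω > 7.1 °/s and
θ > 1.2°; healthy) to the maximal elbow angle, and is cut into 128 ms
windows with 64 ms steps. Each window yields five features per channel —
RMS, zero-cross statistic (ZCR), waveform length (WL), the 4th
autoregressive coefficient (AR4), and mean power frequency (MPF) — i.e. a
20-dimensional feature vector.

Features are standardised and PCA-reduced to ≥95 % explained variance,
then regressed onto the digitised MAS score (0, 1, 1.5, 2) by a
first-order Sugeno ANFIS: for rule *i* with Gaussian memberships
μ(x) = exp(−½((x−c)/δ)²),

    w_i    = ∏_d μ_id(x_d)                 (firing strength)
    w̄_i   = w_i / Σ_j w_j                 (normalisation)
    y(x)   = Σ_i w̄_i (p_iᵀ x + r_i)       (weighted linear consequents)

Rule centers come from subtractive clustering (radius 0.65 on the min-max
scaled input space); consequents are fitted by global linear least
squares. Evaluation is leave-one-subject-out: every fold refits
standardisation, PCA, clustering and consequents on the training subjects
only; a subject's score is the mean window prediction clipped to [0, 2],
compared against the reference via R², RMSE, Cohen's κ (on rounded
levels) and Pearson r.

The TSRT baseline regresses each patient's per-trial reflex-onset angle
(DSRT) against stretch velocity; the zero-velocity intercept is the TSRT
(healthy = 140°), which a within-fold linear calibration maps to a score.

## Worked example

`python examples/04_loso_evaluation.py` generates the default synthetic
cohort (15 subjects: 4 healthy, 3 at MAS 1, 5 at MAS 1+, 3 at MAS 2),
extracts features from the fast stretches and runs the 4-trial protocol:

```
2338 analysis windows from 15 subjects

4-trial protocol, 3 repeats: R^2 = 0.963, RMSE = 0.141

per-subject scores of the first repeat (reference vs predicted MAS):
subject_id   y  y_hat
       H01 0.0   0.05
       P01 1.0   1.01
       P04 1.5   1.56
       P09 2.0   1.76
       ...
```

R² is the coefficient of determination between per-subject reference and
predicted scores over the 15 subjects; RMSE is on the digitised 0–2 MAS
scale, so 0.14 is about a tenth of the scale range. The other examples
walk through cohort simulation (`01`), the signal-to-feature pipeline on a
single trial (`02`), ANFIS construction on a toy surface (`03`), and the
TSRT baseline (`05`).

A thin CLI wraps the same library calls:

```
spastiq simulate --out cohort/ --seed 17
spastiq features --data cohort/ --out features.csv
spastiq evaluate --features features.csv --k 4 --repeats 3 --seed 17 --out report.json
spastiq tsrt --data cohort/ --out tsrt.json
```

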