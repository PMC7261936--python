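"""Synthetic stretch-trial cohorts with planted ground truth.

Clinical stretch-trial recordings of this kind are not publicly
distributable, so this module generates cohorts that carry the statistical
structure the pipeline relies on, with every planted quantity returned in a
truth table:

* **Angle trajectory** — a logistic (sigmoid) rise from the flexed start
  position to the maximal extension (default 140 deg), a short hold, and a
  logistic return, preceded by a quiet lead-in.  Peak extension velocity is
  drawn per velocity class (slow ~30, normal ~90, fast ~180 deg/s, +-20%
  jitter).
* **Gyroscope** — the angle's rate split across three axes by the fixed
  unit direction (2/3, 2/3, -1/3), whose components sum to 1 and have unit
  norm, so the signed sum of axis integrals recovers the joint angle and
  the rate norm recovers |dtheta/dt| exactly.  Axis rates are synthesised
  by inverting the trapezoidal rule, making integration an exact inverse;
  white noise and a constant bias are then added.
* **sEMG** — each channel is band-limited (20-350 Hz) Gaussian background
  noise.  In patient trials the three flexor channels additionally carry a
  stretch-reflex burst that starts once the angle crosses the trial's
  planted onset angle and lasts until maximal extension.  Burst amplitude,
  onset angle and spectral band all depend on the simulated severity:
  higher MAS grade means larger bursts, earlier onset (smaller angle) and a
  band shifted toward higher frequencies; faster stretches also enlarge the
  burst and lower the onset angle (the velocity dependence that defines
  spasticity).  Healthy subjects get no burst.

Cohort composition defaults to the study-scale 15 subjects: 4 healthy
(MAS 0), 3 at MAS 1, 5 at MAS 1+, 3 at MAS 2, with 6 trials per velocity
class per subject (18 total).  Generation is fully deterministic given the
master seed: each trial's RNG is seeded with
``SeedSequence([master_seed, subject_index, trial_index])``.

Generator constants are package defaults chosen to make severity levels
separable but overlapping; they are all exposed on the dataclasses and
carry no claim of physiological calibration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .exceptions import InputError
from .io import CHANNELS, FLEXOR_CHANNELS, TrialRecording, write_trial
from .kinematics import AngleTrajectory

#: nominal peak extension velocity per class (deg/s)
VELOCITY_PEAKS = {"slow": 30.0, "normal": 90.0, "fast": 180.0}

#: per-severity defaults: onset-angle mean (deg), burst gain (x background
#: sigma), burst-band upward shift (Hz)
LEVEL_ONSET_MEAN = {1.0: 95.0, 1.5: 75.0, 2.0: 55.0}
LEVEL_BURST_GAIN = {1.0: 4.0, 1.5: 6.0, 2.0: 8.0}
LEVEL_MPF_SHIFT = {1.0: 20.0, 1.5: 60.0, 2.0: 100.0}

MAS_LABELS = {0.0: "0", 1.0: "1", 1.5: "1+", 2.0: "2"}

#: fixed gyro mounting direction: components sum to 1 (signed axis-angle
#: superposition recovers theta) and have unit norm (rate norm = |theta'|)
GYRO_DIRECTION = np.array([2.0 / 3.0, 2.0 / 3.0, -1.0 / 3.0])


@dataclass
class SubjectProfile:
    """Severity-dependent generator parameters of one simulated subject."""

    subject_id: str
    group: str                       # "patient" | "healthy"
    mas_numeric: float               # 0, 1, 1.5 or 2
    onset_angle_mean: float = float("nan")  # deg; NaN for healthy
    burst_gain: float = 0.0          # burst sigma in units of background sigma
    mpf_shift: float = 0.0           # Hz; upward shift of the burst band
    sigma_bg: float = 8.0            # background sEMG noise SD, uV
    onset_angle_sd: float = 3.0      # trial-to-trial onset jitter, deg
    # Reflex-burst amplitude varies substantially across repeated stretches
    # (coefficients of variation around 30% are typical); this is what makes
    # single-trial assessments unstable and multi-trial averaging worthwhile.
    gain_jitter_sd: float = 0.3      # lognormal SD of per-trial burst gain
    dsrt_velocity_slope: float = 0.08  # deg of onset advance per deg/s of peak velocity
    seed: int = 0


@dataclass
class CohortSpec:
    """Cohort composition and recording parameters."""

    n_per_level: dict = field(
        default_factory=lambda: {0.0: 4, 1.0: 3, 1.5: 5, 2.0: 3}
    )
    trials_per_class: dict = field(
        default_factory=lambda: {"slow": 6, "normal": 6, "fast": 6}
    )
    fs: float = 2000.0
    theta_max: float = 140.0         # maximal elbow extension, deg
    gyro_bias_range: float = 0.3     # per-trial constant bias drawn U(-b, b), deg/s
    gyro_noise_sd: float = 0.5       # white gyro noise SD, deg/s
    master_seed: int = 0


@dataclass
class SynthTrajectory:
    """Analytic ground-truth trajectory of one trial."""

    theta: np.ndarray        # deg
    theta_dot: np.ndarray    # deg/s, signed
    fs: float
    peak_velocity: float     # deg/s (extension phase)

    @property
    def trajectory(self) -> AngleTrajectory:
        return AngleTrajectory(
            theta=self.theta, omega_res=np.abs(self.theta_dot), fs=self.fs
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def make_trajectory(
    velocity_class: str,
    rng: np.random.Generator,
    theta_max: float = 140.0,
    fs: float = 2000.0,
    velocity_jitter: float = 0.2,
) -> SynthTrajectory:
    """Logistic flex->extend->flex angle profile with class-dependent speed."""
    if velocity_class not in VELOCITY_PEAKS:
        raise InputError(f"unknown velocity class {velocity_class!r}")
    vpeak = VELOCITY_PEAKS[velocity_class] * (
        1.0 + rng.uniform(-velocity_jitter, velocity_jitter)
    )
    tau = theta_max / (4.0 * vpeak)          # logistic peak slope = theta_max/(4 tau)
    tau_back = 1.5 * tau                      # return stroke slightly slower
    t1 = 6.0 * tau + 0.3                      # quiet lead-in for baseline stats
    t2 = t1 + 6.0 * tau + 0.5 + 6.0 * tau_back
    duration = t2 + 6.0 * tau_back + 0.3
    t = np.arange(int(round(duration * fs))) / fs
    s1 = _sigmoid((t - t1) / tau)
    s2 = _sigmoid((t - t2) / tau_back)
    profile = s1 - s2
    # normalise so the peak reaches theta_max exactly despite sigmoid tails
    scale = theta_max / float(profile.max())
    theta = scale * profile
    theta -= theta[0]  # start exactly at the flexed reference position
    theta_dot = scale * (s1 * (1 - s1) / tau - s2 * (1 - s2) / tau_back)
    vpeak_actual = float(np.abs(theta_dot).max())
    return SynthTrajectory(theta=theta, theta_dot=theta_dot, fs=fs,
                           peak_velocity=vpeak_actual)


def make_gyro(
    traj: SynthTrajectory,
    rng: np.random.Generator,
    bias: float = 0.0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Three-axis gyro stream whose trapezoidal integral is exactly the angle.

    Each axis angle is ``direction[ax] * theta``; axis rates are obtained by
    inverting the cumulative trapezoid, so the kinematics module recovers
    theta to float precision on noiseless input.  ``bias`` (deg/s) is added
    to the first axis; white noise to all three.
    """
    n = traj.theta.shape[0]
    dt = 1.0 / traj.fs
    g = np.empty((n, 3))
    dtheta = np.diff(traj.theta)
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    for ax in range(3):
        # invert the trapezoid rule: g_k = 2*dtheta_k/dt - g_{k-1}, closed form
        # g_k = (-1)^k (g_0 + sum_{j<=k} (-1)^j * 2*dtheta_j/dt)
        c = 2.0 * GYRO_DIRECTION[ax] * dtheta / dt
        acc = np.concatenate([[0.0], np.cumsum(signs[1:] * c)])
        g[:, ax] = signs * (GYRO_DIRECTION[ax] * traj.theta_dot[0] + acc)
    g[:, 0] += bias
    if noise_sd > 0.0:
        g += rng.normal(0.0, noise_sd, size=g.shape)
    return g


def _band_noise(
    n: int, fs: float, band: tuple[float, float], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian noise with (approximately) the requested SD."""
    white = rng.normal(0.0, 1.0, size=n)
    low = max(band[0], 1.0)
    high = min(band[1], 0.49 * fs)
    sos = _signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def make_semg(
    traj: SynthTrajectory,
    profile: SubjectProfile,
    rng: np.random.Generator,
    theta_max: float = 140.0,
) -> tuple[np.ndarray, float]:
    """Four-channel sEMG for one trial; returns (semg, planted_onset_angle).

    The planted onset angle is NaN for healthy subjects (no burst).  Flexor
    channels (BB, BR, BA) carry the burst with relative gains 1.0/0.85/0.7;
    the extensor (TB) stays at background level.
    """
    n = traj.theta.shape[0]
    fs = traj.fs
    semg = np.column_stack(
        [
            _band_noise(n, fs, (20.0, 350.0), profile.sigma_bg * rng.uniform(0.9, 1.1), rng)
            for _ in CHANNELS
        ]
    )
    if profile.group == "healthy":
        return semg, float("nan")

    onset_angle = (
        profile.onset_angle_mean
        - profile.dsrt_velocity_slope * traj.peak_velocity
        + rng.normal(0.0, profile.onset_angle_sd)
    )
    onset_angle = float(np.clip(onset_angle, 10.0, theta_max - 20.0))

    imax = int(np.argmax(traj.theta))
    crossing = np.flatnonzero(traj.theta[: imax + 1] >= onset_angle)
    if crossing.size == 0:  # pragma: no cover - clip above prevents this
        return semg, float("nan")
    i0 = int(crossing[0])

    envelope = np.zeros(n)
    envelope[i0 : imax + 1] = 1.0
    ramp_up = max(int(round(0.010 * fs)), 2)
    ramp_down = max(int(round(0.030 * fs)), 2)
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_up) / ramp_up))
    envelope[i0 : i0 + ramp_up] = up[: max(0, min(ramp_up, n - i0))]
    end = min(imax + 1, n)
    down = 0.5 * (1 + np.cos(np.pi * np.arange(ramp_down) / ramp_down))
    envelope[end - 1 : end - 1 + ramp_down] = down[: max(0, n - end + 1)]

    gain = (
        profile.burst_gain
        * (1.0 + 0.3 * traj.peak_velocity / 100.0)
        * float(np.exp(rng.normal(0.0, profile.gain_jitter_sd)))
    )
    band = (80.0 + profile.mpf_shift, 160.0 + profile.mpf_shift)
    channel_gain = {0: 1.0, 2: 0.85, 3: 0.7}
    for ch in FLEXOR_CHANNELS:
        burst = _band_noise(n, fs, band, profile.sigma_bg * gain * channel_gain[ch], rng)
        semg[:, ch] += envelope * burst
    return semg, onset_angle


def make_profiles(spec: CohortSpec) -> list[SubjectProfile]:
    """Deterministic subject roster with per-subject trait jitter."""
    profiles = []
    healthy_idx = 0
    patient_idx = 0
    subject_counter = 0
    for level in sorted(spec.n_per_level):
        for _ in range(spec.n_per_level[level]):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.master_seed, 1000 + subject_counter])
            )
            if level == 0.0:
                healthy_idx += 1
                profiles.append(
                    SubjectProfile(
                        subject_id=f"H{healthy_idx:02d}",
                        group="healthy",
                        mas_numeric=0.0,
                        sigma_bg=8.0 * float(np.exp(rng.normal(0.0, 0.1))),
                        seed=subject_counter,
                    )
                )
            else:
                patient_idx += 1
                profiles.append(
                    SubjectProfile(
                        subject_id=f"P{patient_idx:02d}",
                        group="patient",
                        mas_numeric=level,
                        onset_angle_mean=LEVEL_ONSET_MEAN[level] + rng.normal(0.0, 4.0),
                        burst_gain=LEVEL_BURST_GAIN[level] * float(np.exp(rng.normal(0.0, 0.1))),
                        mpf_shift=max(LEVEL_MPF_SHIFT[level] + rng.normal(0.0, 8.0), 0.0),
                        sigma_bg=8.0 * float(np.exp(rng.normal(0.0, 0.1))),
                        seed=subject_counter,
                    )
                )
            subject_counter += 1
    return profiles


def make_trial(
    profile: SubjectProfile,
    velocity_class: str,
    trial_index: int,
    spec: CohortSpec,
    subject_index: int,
) -> tuple[TrialRecording, dict]:
    """Generate one trial and its ground-truth row."""
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.master_seed, subject_index, trial_index])
    )
    traj = make_trajectory(velocity_class, rng, theta_max=spec.theta_max, fs=spec.fs)
    bias = rng.uniform(-spec.gyro_bias_range, spec.gyro_bias_range)
    gyro = make_gyro(traj, rng, bias=bias, noise_sd=spec.gyro_noise_sd)
    semg, onset_angle = make_semg(traj, profile, rng, theta_max=spec.theta_max)
    trial_id = f"{profile.subject_id}_t{trial_index:02d}"
    rec = TrialRecording(
        subject_id=profile.subject_id,
        trial_id=trial_id,
        semg=semg,
        gyro=gyro,
        fs=spec.fs,
        velocity_class=velocity_class,
        mas_label=MAS_LABELS[profile.mas_numeric],
        group=profile.group,
    )
    truth = {
        "subject_id": profile.subject_id,
        "trial_id": trial_id,
        "velocity_class": velocity_class,
        "group": profile.group,
        "mas_numeric": profile.mas_numeric,
        "true_onset_angle": onset_angle,
        "true_peak_velocity": traj.peak_velocity,
        "gyro_bias": bias,
        "n_samples": rec.n_samples,
    }
    return rec, truth


def iter_cohort(spec: CohortSpec | None = None, velocity_classes: tuple[str, ...] | None = None):
    """Yield ``(TrialRecording, truth_row)`` pairs for the whole cohort.

    ``velocity_classes`` restricts generation (e.g. fast-only for the ANFIS
    protocol) without changing any trial's seed or content.
    """
    spec = spec or CohortSpec()
    profiles = make_profiles(spec)
    class_order = ("slow", "normal", "fast")
    for subject_index, profile in enumerate(profiles):
        trial_index = 0
        for vclass in class_order:
            for _ in range(spec.trials_per_class.get(vclass, 0)):
                if velocity_classes is None or vclass in velocity_classes:
                    yield make_trial(profile, vclass, trial_index, spec, subject_index)
                trial_index += 1


def make_cohort(
    spec: CohortSpec | None = None,
    out_dir: str | os.PathLike | None = None,
    velocity_classes: tuple[str, ...] | None = None,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Materialise the cohort; optionally write trial CSVs and the truth table."""
    spec = spec or CohortSpec()
    trials = []
    truth_rows = []
    for rec, truth in iter_cohort(spec, velocity_classes):
        truth_rows.append(truth)
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            write_trial(os.path.join(out_dir, f"{rec.trial_id}.csv"), rec)
        else:
            trials.append(rec)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return trials, truth
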