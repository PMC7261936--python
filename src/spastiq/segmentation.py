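"""Active-segment detection and overlap windowing.

For a patient trial the analysis segment runs from the stretch-reflex sEMG
onset to the sample of maximal elbow angle; for a healthy trial (whose
stretch-reflex threshold lies outside the biomechanical range, so no burst
exists) it runs from the movement onset angle to the maximal angle.

sEMG onset is found with a rectified-envelope double-threshold detector:
the rectified signal is low-pass filtered (zero-phase) into an envelope,
baseline statistics are taken from the first ``baseline_ms`` of the trial,
and the onset is the start of the first envelope excursion that crosses
``mean + h*SD`` and stays above ``mean + h2*SD`` for at least
``min_duration_ms``.  After the high-threshold crossing the onset index is
backtracked to the beginning of its contiguous low-threshold run, which
removes most of the envelope rise-time bias.

Movement onset uses the double kinematic threshold: resultant angular
velocity strictly greater than ``omega_threshold`` (default 7.1 deg/s) AND
joint angle strictly greater than ``theta_threshold`` (default 1.2 deg) —
the peak values observed when an elbow is merely held statically.

Sample indexing is 0-based; segments are half-open ``[start, end)`` with
``end`` at the maximal-angle sample, and sliding windows never extend past
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .exceptions import InputError, OnsetNotFoundError
from .io import FLEXOR_CHANNELS, TrialRecording
from .kinematics import AngleTrajectory


@dataclass(frozen=True)
class OnsetConfig:
    """Envelope double-threshold detector parameters."""

    envelope_cutoff_hz: float = 50.0   # low-pass on the rectified signal
    baseline_ms: float = 250.0         # leading quiet interval for baseline stats
    h: float = 3.0                     # high threshold, baseline SDs above mean
    h2: float = 1.5                    # sustain (low) threshold, baseline SDs
    # The sustain criterion must exceed the envelope's correlation time
    # (~20 ms at a 50 Hz cutoff) by a wide margin, or stationary background
    # noise produces sustained-looking excursions; reflex bursts last
    # hundreds of ms, so 100 ms costs no sensitivity.
    min_duration_ms: float = 100.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Kinematic onset thresholds and window geometry."""

    omega_threshold: float = 7.1       # deg/s, strict
    theta_threshold: float = 1.2       # deg, strict
    window_length: int = 256           # samples (128 ms at 2 kHz)
    window_step: int = 128             # samples (64 ms at 2 kHz)
    onset: OnsetConfig = OnsetConfig()


@dataclass
class StretchSegment:
    """Analysis interval of one trial (half-open sample interval)."""

    start_index: int
    end_index: int
    onset_angle: float
    source: str  # "semg_onset" | "angle_onset"


@dataclass
class AnalysisWindow:
    """One full-length sliding window of multichannel sEMG samples."""

    samples: np.ndarray  # (window_length, 4)
    window_index: int


def detect_semg_onset(
    x: np.ndarray, fs: float, cfg: OnsetConfig | None = None
) -> int | None:
    """Return the burst-onset sample index of one sEMG channel, or None.

    ``x`` must already be band-pass filtered.  Returns ``None`` when the
    envelope never produces a sustained supra-threshold excursion.
    """
    cfg = cfg or OnsetConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InputError("detect_semg_onset expects a single channel")
    n = x.shape[0]
    b_samples = max(int(round(cfg.baseline_ms * fs / 1000.0)), 2)
    if n <= b_samples:
        raise InputError("signal shorter than the baseline window")

    sos = _signal.butter(4, cfg.envelope_cutoff_hz, btype="lowpass", fs=fs, output="sos")
    env = _signal.sosfiltfilt(sos, np.abs(x))

    base = env[:b_samples]
    mu = float(base.mean())
    sd = float(base.std())
    if sd == 0.0:
        sd = np.finfo(float).eps
    hi = mu + cfg.h * sd
    lo = mu + cfg.h2 * sd
    d_samples = max(int(round(cfg.min_duration_ms * fs / 1000.0)), 1)

    above_lo = env > lo
    above_hi = env > hi
    # contiguous runs above the sustain threshold
    edges = np.flatnonzero(np.diff(above_lo.astype(np.int8)))
    starts = np.concatenate([[0] if above_lo[0] else [], edges[~above_lo[edges]] + 1]).astype(int)
    ends = np.concatenate([edges[above_lo[edges]] + 1, [n] if above_lo[-1] else []]).astype(int)
    for s, e in zip(starts, ends):
        if e - s >= d_samples and above_hi[s:e].any():
            return int(s)
    return None


def detect_angle_onset(
    traj: AngleTrajectory,
    omega_threshold: float = SegmentationConfig.omega_threshold,
    theta_threshold: float = SegmentationConfig.theta_threshold,
) -> int:
    """First sample where omega_res > omega_threshold AND theta > theta_threshold."""
    hits = np.flatnonzero(
        (traj.omega_res > omega_threshold) & (traj.theta > theta_threshold)
    )
    if hits.size == 0:
        raise OnsetNotFoundError(
            "trajectory never exceeds the kinematic double threshold (no stretch present)"
        )
    return int(hits[0])


def find_max_angle(traj: AngleTrajectory) -> int:
    """Index of the global maximum joint angle (earliest index on ties)."""
    return int(np.argmax(traj.theta))


def segment_trial(
    rec: TrialRecording,
    traj: AngleTrajectory,
    cfg: SegmentationConfig | None = None,
) -> StretchSegment:
    """Locate the analysis segment of a filtered trial.

    Patients: earliest sEMG onset over the three flexor channels (BB, BR,
    BA) through the maximal-angle sample; falls back to the kinematic onset
    (with a warning) when no burst is detectable.  Healthy subjects: the
    kinematic onset through the maximal-angle sample.
    """
    cfg = cfg or SegmentationConfig()
    end = find_max_angle(traj)
    source = "angle_onset"
    start: int | None = None
    if rec.group == "patient":
        onsets = [
            detect_semg_onset(rec.semg[:, ch], rec.fs, cfg.onset) for ch in FLEXOR_CHANNELS
        ]
        onsets = [o for o in onsets if o is not None]
        if onsets:
            cand = min(onsets)
            if cand < end:
                start, source = cand, "semg_onset"
            else:
                warnings.warn(
                    f"trial {rec.trial_id}: sEMG onset at/after maximal angle; "
                    "falling back to angle onset"
                )
        else:
            warnings.warn(
                f"trial {rec.trial_id}: no sEMG onset detected; falling back to angle onset"
            )
    if start is None:
        start = detect_angle_onset(traj, cfg.omega_threshold, cfg.theta_threshold)
    if start >= end:
        raise InputError(
            f"trial {rec.trial_id}: onset index {start} not before maximal-angle index {end}"
        )
    return StretchSegment(
        start_index=start,
        end_index=end,
        onset_angle=float(traj.theta[start]),
        source=source,
    )


def windows(
    seg: StretchSegment,
    semg: np.ndarray,
    length: int = SegmentationConfig.window_length,
    step: int = SegmentationConfig.window_step,
) -> list[AnalysisWindow]:
    """Cut the segment into overlapping full-length windows.

    Yields ``floor((L - length)/step) + 1`` windows for segment length
    ``L >= length``; a partial tail is discarded, and a too-short segment
    yields zero windows with a warning.
    """
    data = np.asarray(semg, dtype=float)[seg.start_index : seg.end_index]
    L = data.shape[0]
    if L < length:
        warnings.warn(f"segment of {L} samples is shorter than one window ({length}); skipped")
        return []
    count = (L - length) // step + 1
    return [
        AnalysisWindow(samples=data[i * step : i * step + length], window_index=i)
        for i in range(count)
    ]
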