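"""Trial file I/O and the standard pre-processing filter chain.

A stretch trial couples four surface-EMG channels, recorded over the elbow
muscles at 2 kHz, with a 3-axis gyroscope stream from the brachioradialis
sensor that has already been interpolated to the sEMG length.  Channel order
is fixed: biceps brachii (BB), triceps brachii (TB), brachioradialis (BR),
brachialis (BA).

Files are plain CSV with a mandatory header row
``semg_bb,semg_tb,semg_br,semg_ba,gyro_x,gyro_y,gyro_z`` (one row per
sample, '.' decimal separator) plus an optional ``<stem>.meta`` sidecar of
``key=value`` lines carrying subject id, velocity class, MAS label and
group.

The software filter chain applied here is 20-350 Hz band-pass + 50 Hz notch
on sEMG and a 10 Hz low-pass on the gyroscope.  The hardware stage
(amplification, 10-500 Hz analogue filter) is assumed to be already applied
to the recorded files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigError, FormatError, InputError, ParseError

#: fixed channel order (biceps, triceps, brachioradialis, brachialis)
CHANNELS = ("bb", "tb", "br", "ba")
#: indices of the elbow flexors within :data:`CHANNELS` — the spastic muscles
FLEXOR_CHANNELS = (0, 2, 3)

SEMG_COLUMNS = tuple(f"semg_{c}" for c in CHANNELS)
GYRO_COLUMNS = ("gyro_x", "gyro_y", "gyro_z")

VELOCITY_CLASSES = ("slow", "normal", "fast")
GROUPS = ("patient", "healthy")


@dataclass(frozen=True)
class FilterSpec:
    """Pre-processing filter chain parameters.

    band_low/band_high : sEMG band-pass edges in Hz (removes motion artefact
        and ECG below, high-frequency noise above).
    notch : mains interference notch frequency in Hz (quality factor
        ``notch_q``).
    gyro_lowpass : gyroscope low-pass cutoff in Hz.
    order : Butterworth order for band-pass/low-pass stages.
    zero_phase : apply filters forward-backward so onset latencies are not
        shifted.
    """

    band_low: float = 20.0
    band_high: float = 350.0
    notch: float = 50.0
    notch_q: float = 30.0
    gyro_lowpass: float = 10.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0.0 < self.band_low < self.band_high):
            raise ConfigError(
                f"band edges must satisfy 0 < low < high, got ({self.band_low}, {self.band_high})"
            )
        if self.band_high >= fs / 2.0:
            raise ConfigError(
                f"band_high={self.band_high} Hz is not below Nyquist ({fs / 2.0} Hz)"
            )
        if not (0.0 < self.notch < fs / 2.0):
            raise ConfigError(f"notch={self.notch} Hz must lie inside (0, Nyquist)")


@dataclass
class TrialRecording:
    """One passive-stretch trial.

    ``semg`` is an ``(n, 4)`` matrix in microvolts (channel order
    :data:`CHANNELS`); ``gyro`` is ``(n, 3)`` in degrees/second, already
    resampled to the sEMG length.
    """

    subject_id: str
    trial_id: str
    semg: np.ndarray
    gyro: np.ndarray
    fs: float = 2000.0
    velocity_class: str = "fast"
    mas_label: str | None = None
    group: str = "patient"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.semg = np.asarray(self.semg, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.semg.ndim != 2 or self.semg.shape[1] != len(CHANNELS):
            raise InputError(f"semg must be (n, 4), got {self.semg.shape}")
        if self.gyro.ndim != 2 or self.gyro.shape[1] != 3:
            raise InputError(f"gyro must be (n, 3), got {self.gyro.shape}")
        if self.semg.shape[0] != self.gyro.shape[0]:
            raise InputError(
                f"semg and gyro row counts differ: {self.semg.shape[0]} vs {self.gyro.shape[0]}"
            )
        if not self.fs > 0:
            raise InputError(f"fs must be positive, got {self.fs}")
        if self.velocity_class not in VELOCITY_CLASSES:
            raise InputError(f"unknown velocity_class {self.velocity_class!r}")
        if self.group not in GROUPS:
            raise InputError(f"unknown group {self.group!r}")

    @property
    def n_samples(self) -> int:
        return self.semg.shape[0]

    def filtered(self, spec: FilterSpec | None = None) -> "TrialRecording":
        """Return a copy with the software filter chain applied."""
        spec = spec or FilterSpec()
        return replace(
            self,
            semg=filter_semg(self.semg, self.fs, spec),
            gyro=filter_gyro(self.gyro, self.fs, spec.gyro_lowpass, order=spec.order,
                             zero_phase=spec.zero_phase),
        )


# ---------------------------------------------------------------------------
# file I/O


def _meta_path(path: str | os.PathLike) -> str:
    base, _ = os.path.splitext(os.fspath(path))
    return base + ".meta"


def read_meta(path: str | os.PathLike) -> dict:
    """Parse a ``key=value`` sidecar metadata file."""
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"metadata line without '=': {line!r}")
            key, value = line.split("=", 1)
            meta[key.strip()] = value.strip()
    return meta


def write_meta(path: str | os.PathLike, meta: Mapping[str, object]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"{key}={value}\n")


def read_trial(path: str | os.PathLike, meta: Mapping[str, object] | None = None) -> TrialRecording:
    """Read one trial CSV (plus sidecar metadata) into a :class:`TrialRecording`.

    ``meta`` overrides/extends the sidecar; recognised keys are
    ``subject_id``, ``trial_id``, ``fs``, ``velocity_class``, ``mas_label``,
    ``group``.
    """
    df = pd.read_csv(path)
    required = SEMG_COLUMNS + GYRO_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in required:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(bad.idxmax()) if bad.any() else int(coerced.isna().idxmax())
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")

    info: dict = {}
    sidecar = _meta_path(path)
    if os.path.exists(sidecar):
        info.update(read_meta(sidecar))
    if meta:
        info.update(meta)

    stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    mas = info.get("mas_label")
    return TrialRecording(
        subject_id=str(info.get("subject_id", stem)),
        trial_id=str(info.get("trial_id", stem)),
        semg=df[list(SEMG_COLUMNS)].to_numpy(dtype=float),
        gyro=df[list(GYRO_COLUMNS)].to_numpy(dtype=float),
        fs=float(info.get("fs", 2000.0)),
        velocity_class=str(info.get("velocity_class", "fast")),
        mas_label=None if mas in (None, "", "None") else str(mas),
        group=str(info.get("group", "patient")),
        meta=info,
    )


def write_trial(path: str | os.PathLike, rec: TrialRecording, sidecar: bool = True) -> None:
    """Write a trial to CSV (full float precision, lossless round-trip)."""
    df = pd.DataFrame(
        np.hstack([rec.semg, rec.gyro]),
        columns=list(SEMG_COLUMNS + GYRO_COLUMNS),
    )
    df.to_csv(path, index=False)
    if sidecar:
        write_meta(
            _meta_path(path),
            {
                "subject_id": rec.subject_id,
                "trial_id": rec.trial_id,
                "fs": rec.fs,
                "velocity_class": rec.velocity_class,
                "mas_label": "" if rec.mas_label is None else rec.mas_label,
                "group": rec.group,
            },
        )


# ---------------------------------------------------------------------------
# filtering


def _apply(sos_or_ba, x: np.ndarray, zero_phase: bool, is_sos: bool) -> np.ndarray:
    if is_sos:
        return signal.sosfiltfilt(sos_or_ba, x, axis=0) if zero_phase else signal.sosfilt(
            sos_or_ba, x, axis=0
        )
    b, a = sos_or_ba
    return signal.filtfilt(b, a, x, axis=0) if zero_phase else signal.lfilter(b, a, x, axis=0)


def filter_semg(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Band-pass + mains-notch filter an sEMG array (samples on axis 0)."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    sos = signal.butter(
        spec.order, [spec.band_low, spec.band_high], btype="bandpass", fs=fs, output="sos"
    )
    y = _apply(sos, x, spec.zero_phase, is_sos=True)
    ba = signal.iirnotch(spec.notch, spec.notch_q, fs=fs)
    y = _apply(ba, y, spec.zero_phase, is_sos=False)
    return y[:, 0] if one_d else y


def filter_gyro(
    g: np.ndarray, fs: float, cutoff: float = 10.0, order: int = 4, zero_phase: bool = True
) -> np.ndarray:
    """Low-pass filter gyroscope data (DC preserved)."""
    if not 0.0 < cutoff < fs / 2.0:
        raise ConfigError(f"cutoff={cutoff} Hz must lie inside (0, Nyquist={fs / 2.0})")
    g = np.asarray(g, dtype=float)
    one_d = g.ndim == 1
    if one_d:
        g = g[:, None]
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    y = _apply(sos, g, zero_phase, is_sos=True)
    return y[:, 0] if one_d else y


def resample_gyro(g: np.ndarray, fs_gyro: float, n_target: int, fs_target: float) -> np.ndarray:
    """Linearly interpolate a raw (e.g. 400 Hz) gyro stream onto the sEMG grid."""
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if g.shape[0] == 1 and g.size > 3:
        g = g.T
    t_src = np.arange(g.shape[0]) / fs_gyro
    t_dst = np.arange(n_target) / fs_target
    return np.column_stack([np.interp(t_dst, t_src, g[:, j]) for j in range(g.shape[1])])
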