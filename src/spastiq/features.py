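"""Per-window sEMG features.

Five features per channel, 20 per window over the four channels, in the
fixed order (RMS, ZCR, WL, AR4, MPF) x (BB, TB, BR, BA):

* RMS — root mean square, ``sqrt(mean(w^2))``; amplitude scale.
* ZCR — implemented literally as the windowed statistic
  ``(1/(M-1)) * sum_k sign(w_k * w_{k+1})`` with ``sign(x) = 1`` for
  ``x > 0`` and 0 otherwise, i.e. the fraction of strictly same-sign
  adjacent pairs.  This is an affine transform of the conventional
  zero-crossing rate (available via ``conventional=True``), so downstream
  modelling is unaffected by the choice.
* WL — waveform length, ``sum_k |w_{k+1} - w_k|``.
* AR4 — the 4th coefficient of a 4th-order autoregressive fit
  (Yule-Walker); the full coefficient set and residual variance are kept in
  :class:`ARFit` for inspection.
* MPF — mean power frequency, the power-weighted mean of an unwindowed
  periodogram of the window.

No amplitude normalisation (e.g. MVC) is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from statsmodels.regression.linear_model import yule_walker

from .exceptions import InputError
from .io import CHANNELS

FEATURE_BASENAMES = ("rms", "zcr", "wl", "ar4", "mpf")
#: 20 feature-column names in canonical (feature x channel) order
FEATURE_NAMES = tuple(f"{f}_{c}" for f in FEATURE_BASENAMES for c in CHANNELS)

AR_ORDER = 4


@dataclass
class ARFit:
    """Autoregressive fit: coefficients a_1..a_q and residual variance."""

    coefficients: np.ndarray
    residual_variance: float


@dataclass
class FeatureVector:
    """One window's 20 features plus provenance labels."""

    values: np.ndarray
    window_index: int
    subject_id: str = ""
    trial_id: str = ""
    mas_numeric: float = float("nan")


def rms(w: np.ndarray) -> float:
    """Root mean square of the window."""
    w = np.asarray(w, dtype=float)
    if w.size < 1:
        raise InputError("rms of an empty window")
    return float(np.sqrt(np.mean(w * w)))


def zcr(w: np.ndarray, conventional: bool = False) -> float:
    """Adjacent-pair sign statistic (default) or conventional crossing rate."""
    w = np.asarray(w, dtype=float)
    m = w.size
    if m < 2:
        raise InputError("zcr needs at least 2 samples")
    prod = w[:-1] * w[1:]
    if conventional:
        return float(np.count_nonzero(prod < 0.0) / (m - 1))
    return float(np.count_nonzero(prod > 0.0) / (m - 1))


def wl(w: np.ndarray) -> float:
    """Waveform length: cumulative absolute sample-to-sample excursion."""
    w = np.asarray(w, dtype=float)
    if w.size < 2:
        raise InputError("wl needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(w))))


def ar4(w: np.ndarray, order: int = AR_ORDER) -> ARFit:
    """Yule-Walker AR(order) fit of the window.

    A constant (degenerate) window cannot support an AR fit; it yields
    all-zero coefficients with a warning, so the exported feature is 0.
    """
    w = np.asarray(w, dtype=float)
    if w.size <= 2 * order:
        raise InputError(f"ar4 needs more than {2 * order} samples")
    if np.ptp(w) == 0.0:
        warnings.warn("constant window: AR coefficients set to 0")
        return ARFit(coefficients=np.zeros(order), residual_variance=0.0)
    rho, sigma = yule_walker(w, order=order, method="mle", demean=True)
    return ARFit(coefficients=np.asarray(rho, dtype=float), residual_variance=float(sigma**2))


def mpf(w: np.ndarray, fs: float) -> float:
    """Mean power frequency of the window's periodogram (Hz).

    Unwindowed (boxcar) periodogram up to Nyquist; zero total power yields
    0 with a warning.
    """
    w = np.asarray(w, dtype=float)
    if w.size < 2:
        raise InputError("mpf needs at least 2 samples")
    freqs, power = periodogram(w, fs=fs, window="boxcar", detrend=False)
    total = float(power.sum())
    if total == 0.0:
        warnings.warn("zero-power window: MPF set to 0")
        return 0.0
    return float(np.sum(freqs * power) / total)


def extract_features(
    samples: np.ndarray, fs: float, conventional_zcr: bool = False
) -> np.ndarray:
    """Compute the 20-element feature vector of one (M, 4) analysis window.

    Ordered as :data:`FEATURE_NAMES`: each feature across the four channels,
    features in (RMS, ZCR, WL, AR4, MPF) order.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != len(CHANNELS):
        raise InputError(f"expected an (M, 4) window, got {samples.shape}")
    cols = [samples[:, ch] for ch in range(samples.shape[1])]
    values: list[float] = []
    values += [rms(c) for c in cols]
    values += [zcr(c, conventional=conventional_zcr) for c in cols]
    values += [wl(c) for c in cols]
    values += [float(ar4(c).coefficients[-1]) for c in cols]
    values += [mpf(c, fs) for c in cols]
    return np.asarray(values, dtype=float)
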