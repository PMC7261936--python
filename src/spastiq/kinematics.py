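"""Elbow joint-angle reconstruction from 3-axis gyroscope data.

The elbow is treated as a single hinge: each gyro axis is integrated
(trapezoidal rule) into an axis angle, and the joint angle is the signed sum
of the three axis angles (extension positive, zero at the flexed start
position).  The resultant angular velocity is the Euclidean norm of the
three instantaneous axis rates.

Because a passive stretch returns the arm to its start posture, integration
drift is removed by subtracting the linear ramp that maps the raw endpoint
back onto the start angle (two-point detrend); only the endpoint constraint
is assumed, nothing about the drift shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import InputError


@dataclass
class AngleTrajectory:
    """Joint-angle series (degrees) and resultant angular velocity (deg/s)."""

    theta: np.ndarray
    omega_res: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega_res = np.asarray(self.omega_res, dtype=float)
        if self.theta.shape != self.omega_res.shape:
            raise InputError("theta and omega_res must have the same length")

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def integrate_gyro(g: np.ndarray, fs: float) -> AngleTrajectory:
    """Integrate an ``(n, 3)`` gyro matrix (deg/s) into an :class:`AngleTrajectory`.

    Per-axis cumulative trapezoidal integrals are summed into the joint
    angle; ``omega_res`` is the per-sample Euclidean norm of the three rates
    (always >= 0).
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise InputError(f"gyro must be (n, 3), got {g.shape}")
    if g.shape[0] < 2:
        raise InputError("need at least 2 samples to integrate")
    dt = 1.0 / fs
    axis_angles = cumulative_trapezoid(g, dx=dt, axis=0, initial=0.0)
    theta = axis_angles.sum(axis=1)
    omega_res = np.linalg.norm(g, axis=1)
    return AngleTrajectory(theta=theta, omega_res=omega_res, fs=fs)


def correct_drift(traj: AngleTrajectory) -> AngleTrajectory:
    """Remove integration drift via the endpoint-consistency constraint.

    Subtracts the linear ramp r with r[0] = 0 and r[T] = theta[T] - theta[0]
    (plus the start offset), so the corrected angle starts and ends at 0.
    Idempotent; ``omega_res`` is untouched.
    """
    theta = traj.theta
    n = theta.shape[0]
    if n < 2:
        raise InputError("need at least 2 samples")
    ramp = theta[0] + (theta[-1] - theta[0]) * np.arange(n) / (n - 1)
    return replace(traj, theta=theta - ramp)
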