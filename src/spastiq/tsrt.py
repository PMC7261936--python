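"""Tonic stretch-reflex threshold (TSRT) baseline.

The dynamic stretch-reflex threshold (DSRT) of one trial is the elbow angle
at which the stretch-reflex sEMG burst begins during a passive stretch at a
given velocity; spastic muscles fire earlier (smaller angles) at faster
stretches.  Regressing DSRT against stretch velocity across trials at all
three velocity classes and extrapolating to zero velocity gives the TSRT —
the tonic recruitment threshold.  Lower TSRT means more severe spasticity;
a healthy elbow's threshold lies beyond the biomechanical range, so healthy
subjects are assigned the conventional 140 degrees.

Per-trial stretch velocity is summarised as the peak resultant angular
velocity over the stretch (a mean-velocity alternative is available).  The
TSRT-to-score mapping is a within-fold linear calibration of the digitised
MAS score on the TSRT angle, used inside the same leave-one-subject-out
loop as the ANFIS method; it is a documented stand-in for the published
threshold-scoring procedure, not a reproduction of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import (
    EvaluationReport,
    cohen_kappa,
    pearson_r,
    r_squared,
    rmse,
    round_to_levels,
)
from .exceptions import DegenerateFitError, InputError
from .io import FLEXOR_CHANNELS, TrialRecording
from .kinematics import correct_drift, integrate_gyro
from .pipeline import PipelineConfig
from .segmentation import detect_semg_onset, find_max_angle

HEALTHY_TSRT_DEG = 140.0


@dataclass
class DsrtPoint:
    """One trial's dynamic threshold: (stretch velocity, onset angle)."""

    velocity: float      # deg/s
    dsrt_angle: float    # deg


@dataclass
class TsrtEstimate:
    """Zero-velocity intercept of the DSRT-velocity regression."""

    tsrt_angle: float
    slope: float
    n_points: int
    residual: float


def dsrt_of_trial(
    rec: TrialRecording,
    cfg: PipelineConfig | None = None,
    velocity_measure: str = "peak",
) -> DsrtPoint | None:
    """Extract the DSRT point of one patient trial (None when no burst is found)."""
    cfg = cfg or PipelineConfig()
    filtered = rec if cfg.prefiltered else rec.filtered(cfg.filter)
    traj = correct_drift(integrate_gyro(filtered.gyro, filtered.fs))
    end = find_max_angle(traj)
    onsets = [
        detect_semg_onset(filtered.semg[:, ch], filtered.fs, cfg.segmentation.onset)
        for ch in FLEXOR_CHANNELS
    ]
    onsets = [o for o in onsets if o is not None and o < end]
    if not onsets:
        warnings.warn(f"trial {rec.trial_id}: no sEMG onset; excluded from TSRT fit")
        return None
    onset = min(onsets)
    stretch_omega = traj.omega_res[: end + 1]
    if velocity_measure == "peak":
        velocity = float(np.max(stretch_omega))
    elif velocity_measure == "mean":
        velocity = float(np.mean(stretch_omega))
    else:
        raise InputError(f"unknown velocity measure {velocity_measure!r}")
    return DsrtPoint(velocity=velocity, dsrt_angle=float(traj.theta[onset]))


def fit_tsrt(points: list[DsrtPoint]) -> TsrtEstimate:
    """Ordinary least-squares line dsrt = slope*velocity + intercept.

    The TSRT is the intercept (velocity -> 0).  Requires at least two
    points at distinct velocities.
    """
    if len(points) < 2:
        raise InputError("fit_tsrt needs at least 2 DSRT points")
    v = np.array([p.velocity for p in points], dtype=float)
    a = np.array([p.dsrt_angle for p in points], dtype=float)
    if np.ptp(v) == 0.0:
        raise DegenerateFitError("all stretch velocities identical: TSRT fit is degenerate")
    A = np.column_stack([v, np.ones_like(v)])
    coef, *_ = np.linalg.lstsq(A, a, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = A @ coef - a
    return TsrtEstimate(
        tsrt_angle=intercept,
        slope=slope,
        n_points=len(points),
        residual=float(np.sqrt(np.mean(resid**2))),
    )


def tsrt_of_subject(
    rec_list: list[TrialRecording],
    group: str,
    cfg: PipelineConfig | None = None,
) -> TsrtEstimate:
    """Subject-level TSRT: fixed 140 deg for healthy, fitted line for patients."""
    if group == "healthy":
        return TsrtEstimate(tsrt_angle=HEALTHY_TSRT_DEG, slope=0.0, n_points=0, residual=0.0)
    points = [p for p in (dsrt_of_trial(r, cfg) for r in rec_list) if p is not None]
    return fit_tsrt(points)


def tsrt_table_from_trials(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject TSRT estimates from a pipeline trial table.

    Patient rows must carry ``onset_angle``/``peak_velocity`` with
    ``onset_source == "semg_onset"`` (other rows are excluded from the fit,
    mirroring :func:`dsrt_of_trial`).
    """
    rows = []
    for subject in sorted(trial_table["subject_id"].unique()):
        sub = trial_table[trial_table["subject_id"] == subject]
        group = sub["group"].iloc[0]
        mas = float(sub["mas_numeric"].iloc[0])
        if group == "healthy":
            est = TsrtEstimate(HEALTHY_TSRT_DEG, 0.0, 0, 0.0)
        else:
            pts = [
                DsrtPoint(velocity=row.peak_velocity, dsrt_angle=row.onset_angle)
                for row in sub.itertuples()
                if row.onset_source == "semg_onset"
            ]
            if len(pts) < 2:
                warnings.warn(f"subject {subject}: fewer than 2 DSRT points; excluded")
                continue
            est = fit_tsrt(pts)
        rows.append(
            {
                "subject_id": subject,
                "group": group,
                "mas_numeric": mas,
                "tsrt_angle": est.tsrt_angle,
                "slope": est.slope,
                "n_points": est.n_points,
                "residual": est.residual,
            }
        )
    return pd.DataFrame(rows)


def tsrt_to_score(
    train: list[tuple[float, float]], test_angle: float,
    clip: tuple[float, float] | None = (0.0, 2.0),
) -> float:
    """Linear calibration of MAS score on TSRT angle, evaluated at test_angle."""
    if len(train) < 2:
        raise InputError("tsrt_to_score needs at least 2 training subjects")
    angles = np.array([a for a, _ in train], dtype=float)
    scores = np.array([s for _, s in train], dtype=float)
    if np.ptp(angles) == 0.0:
        raise DegenerateFitError("all training TSRT angles identical")
    A = np.column_stack([angles, np.ones_like(angles)])
    coef, *_ = np.linalg.lstsq(A, scores, rcond=None)
    pred = float(coef[0] * test_angle + coef[1])
    if clip is not None:
        pred = float(np.clip(pred, *clip))
    return pred


def tsrt_loso_evaluate(tsrt_table: pd.DataFrame) -> EvaluationReport:
    """Leave-one-subject-out evaluation of the TSRT-to-score baseline."""
    if len(tsrt_table) < 2:
        raise InputError("need at least 2 subjects")
    rows = []
    for i, row in tsrt_table.iterrows():
        train = tsrt_table.drop(index=i)
        pred = tsrt_to_score(
            list(zip(train["tsrt_angle"], train["mas_numeric"])), float(row["tsrt_angle"])
        )
        rows.append({"subject_id": row["subject_id"], "y": float(row["mas_numeric"]),
                     "y_hat": pred})
    scores = pd.DataFrame(rows)
    y = scores["y"].to_numpy()
    y_hat = scores["y_hat"].to_numpy()
    return EvaluationReport(
        subjects=scores,
        r2=r_squared(y, y_hat),
        rmse=rmse(y, y_hat),
        kappa=cohen_kappa(round_to_levels(y), round_to_levels(y_hat)),
        pearson_r=pearson_r(y, y_hat),
        config={"method": "tsrt"},
    )
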