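"""Trial-to-feature-table plumbing shared by the ANFIS and TSRT methods.

``build_feature_table`` runs each trial through the filter chain, angle
reconstruction, segment detection, overlap windowing and feature
extraction, and returns two data frames:

* a **window table** — one row per analysis window: the 20 feature columns
  plus subject/trial metadata and the digitised MAS score; this is what
  :func:`spastiq.evaluation.loso_evaluate` consumes;
* a **trial table** — one row per trial with the detected onset
  (index/angle/source) and peak resultant angular velocity; this is what
  the TSRT baseline consumes.

Trials can be supplied as any iterable of :class:`~spastiq.io.TrialRecording`
(a generator keeps memory flat for large synthetic cohorts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .evaluation import digitize_mas
from .features import FEATURE_NAMES, extract_features
from .io import FilterSpec, TrialRecording
from .kinematics import correct_drift, integrate_gyro
from .segmentation import SegmentationConfig, segment_trial, windows


@dataclass(frozen=True)
class PipelineConfig:
    """Pre-processing and segmentation parameters for table building."""

    filter: FilterSpec = FilterSpec()
    segmentation: SegmentationConfig = SegmentationConfig()
    conventional_zcr: bool = False
    prefiltered: bool = False  # inputs already ran through the filter chain


def process_trial(
    rec: TrialRecording, cfg: PipelineConfig | None = None
) -> tuple[list[dict], dict]:
    """Process one trial into window feature rows and a trial summary row."""
    cfg = cfg or PipelineConfig()
    filtered = rec if cfg.prefiltered else rec.filtered(cfg.filter)
    traj = correct_drift(integrate_gyro(filtered.gyro, filtered.fs))
    seg = segment_trial(filtered, traj, cfg.segmentation)
    win_list = windows(
        seg, filtered.semg, cfg.segmentation.window_length, cfg.segmentation.window_step
    )
    mas = float("nan") if rec.mas_label is None else digitize_mas(rec.mas_label)
    meta = {
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "velocity_class": rec.velocity_class,
        "group": rec.group,
        "mas_numeric": mas,
    }
    win_rows = []
    for w in win_list:
        row = dict(meta)
        row["window_index"] = w.window_index
        row.update(zip(FEATURE_NAMES, extract_features(w.samples, filtered.fs,
                                                       cfg.conventional_zcr)))
        win_rows.append(row)
    peak_velocity = float(np.max(traj.omega_res[: seg.end_index + 1]))
    trial_row = dict(meta)
    trial_row.update(
        {
            "onset_index": seg.start_index,
            "onset_angle": seg.onset_angle,
            "onset_source": seg.source,
            "max_angle_index": seg.end_index,
            "max_angle": float(traj.theta[seg.end_index]),
            "peak_velocity": peak_velocity,
            "n_windows": len(win_rows),
        }
    )
    return win_rows, trial_row


def build_feature_table(
    trials: Iterable[TrialRecording], cfg: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the feature pipeline over trials; returns (window_table, trial_table)."""
    cfg = cfg or PipelineConfig()
    win_rows: list[dict] = []
    trial_rows: list[dict] = []
    for rec in trials:
        try:
            w, t = process_trial(rec, cfg)
        except Exception as exc:  # pragma: no cover - defensive logging path
            warnings.warn(f"trial {rec.trial_id} skipped: {exc}")
            continue
        win_rows.extend(w)
        trial_rows.append(t)
    window_table = pd.DataFrame(win_rows)
    trial_table = pd.DataFrame(trial_rows)
    return window_table, trial_table
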