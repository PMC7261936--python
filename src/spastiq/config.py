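"""Run configuration: one plain-text (YAML) document with validated keys.

Every tunable constant of the pipeline — filter bands, the kinematic onset
double threshold (7.1 deg/s, 1.2 deg), window geometry (256/128 samples),
the PCA variance target (0.95), the clustering radius (0.65) and squash
factor (1.5), the healthy-subject TSRT (140 deg) — lives in the dataclass
defaults here and in the module-level dataclasses they compose; pipeline
logic never hard-codes them.  A YAML file may override any subset; unknown
keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .anfis import ClusteringConfig
from .evaluation import EvaluationConfig
from .exceptions import ConfigError
from .io import FilterSpec
from .pipeline import PipelineConfig
from .segmentation import OnsetConfig, SegmentationConfig


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    filter: FilterSpec = FilterSpec()
    onset: OnsetConfig = OnsetConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    pca_var_target: float = 0.95
    clustering: ClusteringConfig = ClusteringConfig()
    training_mode: str = "lse"
    epochs: int = 20
    k: int = 4
    repeats: int = 3
    seed: int = 0
    healthy_tsrt_deg: float = 140.0
    conventional_zcr: bool = False

    def pipeline_config(self) -> PipelineConfig:
        seg = dataclasses.replace(self.segmentation, onset=self.onset)
        return PipelineConfig(
            filter=self.filter, segmentation=seg, conventional_zcr=self.conventional_zcr
        )

    def evaluation_config(self) -> EvaluationConfig:
        return EvaluationConfig(
            pca_var_target=self.pca_var_target,
            clustering=self.clustering,
            training_mode=self.training_mode,
            epochs=self.epochs,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "filter", "onset", "segmentation", "clustering"
        ):
            sub_cls = {
                "filter": FilterSpec,
                "onset": OnsetConfig,
                "segmentation": SegmentationConfig,
                "clustering": ClusteringConfig,
            }[f.name]
            if not isinstance(value, dict):
                raise ConfigError(f"{path}.{f.name} must be a mapping")
            kwargs[f.name] = _build(sub_cls, value, f"{path}.{f.name}")
        else:
            kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | None = None) -> RunConfig:
    """Load a RunConfig from YAML (defaults when ``path`` is None)."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return _build(RunConfig, data, "config")


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
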