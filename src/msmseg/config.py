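"""Pipeline configuration: documented defaults, YAML round-trip, validation.

Unknown keys are rejected so typos in config files fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from typing import List, Optional

import yaml


@dataclass(frozen=True)
class DiffusionConfig:
    K: float = 15.0
    lam: float = 1.0
    iterations: int = 10


@dataclass(frozen=True)
class PreprocessConfig:
    tophat_diameter: int = 11
    clahe_tile: int = 16
    clahe_clip: float = 2.0
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)


@dataclass(frozen=True)
class OversegmentationConfig:
    gaussian_sigma: float = 1.0
    #: which image the superpixel means are taken from: the diffusion result
    #: ("diffused") or the raw input slice ("raw")
    intensity_source: str = "diffused"


@dataclass(frozen=True)
class MergingConfig:
    thresholds: List[float] = field(
        default_factory=lambda: [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0])
    order: str = "desc"
    stability_aggregate: str = "mean"


@dataclass(frozen=True)
class SemanticsConfig:
    tqual: float = 0.97
    boundary_mode: str = "segment-mean"
    perimeter: str = "crofton"
    #: normalization constant for the stability feature (number of thresholds)
    msm_max: float = 7.0
    i_max: float = 255.0


@dataclass(frozen=True)
class EvaluationConfig:
    sweep_start: float = 0.900
    sweep_stop: float = 1.000
    sweep_points: int = 21
    min_overlap_px: int = 1
    register_min_dc: float = 0.75


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    oversegmentation: OversegmentationConfig = field(
        default_factory=OversegmentationConfig)
    merging: MergingConfig = field(default_factory=MergingConfig)
    semantics: SemanticsConfig = field(default_factory=SemanticsConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: Optional[dict]) -> "PipelineConfig":
        return _build(cls, data or {}, path="")

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))


def _build(dc_type, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    known = {f.name: f for f in fields(dc_type)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under {path or '<root>'}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        sub = _SUBSECTIONS.get((dc_type, name))
        if sub is not None:
            kwargs[name] = _build(sub, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    return dc_type(**kwargs)


_SUBSECTIONS = {
    (PipelineConfig, "preprocess"): PreprocessConfig,
    (PipelineConfig, "oversegmentation"): OversegmentationConfig,
    (PipelineConfig, "merging"): MergingConfig,
    (PipelineConfig, "semantics"): SemanticsConfig,
    (PipelineConfig, "evaluation"): EvaluationConfig,
    (PreprocessConfig, "diffusion"): DiffusionConfig,
}
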