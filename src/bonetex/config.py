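"""Pipeline configuration.

A single YAML file fully determines a run: ROI thresholds, quantization
levels, GLCM options, which models to fit, ANN training settings, the
evaluation targets and the seed.  Every run writes its resolved config next
to the outputs for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features import DEFAULT_LEVELS, Direction, FeatureConfig
from .models import AnnTrainingConfig
from .roi import DEFAULT_HU_HIGH, DEFAULT_HU_LOW, DEFAULT_MIN_ROI_AREA

__all__ = ["RoiConfig", "PipelineConfig"]


@dataclass
class RoiConfig:
    hu_low: float = DEFAULT_HU_LOW
    hu_high: float = DEFAULT_HU_HIGH
    closing: bool = True
    min_roi_area: int = DEFAULT_MIN_ROI_AREA


@dataclass
class PipelineConfig:
    roi: RoiConfig = field(default_factory=RoiConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    ann: AnnTrainingConfig = field(default_factory=AnnTrainingConfig)
    models: tuple[str, ...] = ("linear", "ann")
    targets: tuple[str, ...] = ("lumbar_total", "lumbar_total_excl_L1", "hip_total")
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in ("linear", "ann"):
                raise ValueError(f"unknown model {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "roi" in raw:
            kwargs["roi"] = RoiConfig(**raw["roi"])
        if "features" in raw:
            f = dict(raw["features"])
            if "levels" in f:
                f["levels"] = tuple(f["levels"])
            if "directions" in f:
                f["directions"] = tuple(Direction(d) for d in f["directions"])
            kwargs["features"] = FeatureConfig(**f)
        if "ann" in raw:
            kwargs["ann"] = AnnTrainingConfig(**raw["ann"])
        for key in ("models", "targets"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("seed", "strict"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"]["directions"] = [dir_.value for dir_ in self.features.directions]
        d["features"]["levels"] = list(self.features.levels)
        d["models"] = list(self.models)
        d["targets"] = list(self.targets)
        return d

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
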