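"""Typed pipeline configuration with a strict (unknown-keys-rejected) schema."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import SpecificationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSection(_Strict):
    low_cut: float = 0.5
    high_cut: float = 40.0
    num_taps: int = 101


class RPeakSection(_Strict):
    refractory_s: float = 0.2


class SegmentSection(_Strict):
    pre: int = 69
    post: int = 130


class FeatureSection(_Strict):
    wavelet: str = "db4"


class ModelSection(_Strict):
    kind: str = "random_forest"
    n_trees: int = 10


class StreamingSection(_Strict):
    trigger_interval: float = 5.0
    carry_over: bool = True
    realtime: bool = False


class PipelineConfig(_Strict):
    seed: int = 0
    filter: FilterSection = FilterSection()
    rpeak: RPeakSection = RPeakSection()
    segment: SegmentSection = SegmentSection()
    features: FeatureSection = FeatureSection()
    model: ModelSection = ModelSection()
    streaming: StreamingSection = StreamingSection()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; unknown keys are an error, not a warning."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise SpecificationError(f"invalid configuration: {exc}") from exc
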