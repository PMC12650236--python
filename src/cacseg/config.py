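"""Typed run configuration with strict YAML round-tripping.

Every pinned default the underlying method leaves open (window bounds,
fusion weights, top-k, dilation radii, ...) lives here so a run's manifest
records the full experimental condition. Unknown keys are rejected rather
than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .preprocess import ConfigError

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class PreprocessBlock:
    window: tuple[float, float] = (-1024.0, 3071.0)
    target_spacing_mm: float = 1.0
    normalization: str = "minmax"


@dataclass
class VesselnessBlock:
    scales_mm: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
    alpha: float = 0.5
    beta: float = 0.5
    c: float | str = "auto"
    mode: str = "stack"            # or "blend"
    blend_weight: float = 0.5


@dataclass
class ModelBlock:
    depth: int = 2
    base_channels: int = 8
    in_channels: int = 1
    out_channels: int = 1


@dataclass
class TrainBlock:
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    positive_slice_only: bool = True
    augment: str = "none"


@dataclass
class CascadeBlock:
    margin_mm: float = 10.0
    prior_dilation_mm: float = 2.0
    min_component_voxels: int = 10


@dataclass
class FusionBlock:
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    top_k: int = 2
    member_threshold: float = 0.5
    output_threshold: float = 0.5
    s_min: int = 3
    use_prior: bool = True


@dataclass
class AgatstonBlock:
    min_hu: float = 130.0
    min_area_mm2: float = 1.0
    slice_thickness_mm: float = 3.0
    normalize_thickness: bool = False


@dataclass
class EvalBlock:
    average: str = "micro"         # or "macro"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    vesselness: VesselnessBlock = field(default_factory=VesselnessBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    train: TrainBlock = field(default_factory=TrainBlock)
    cascade: CascadeBlock = field(default_factory=CascadeBlock)
    fusion: FusionBlock = field(default_factory=FusionBlock)
    agatston: AgatstonBlock = field(default_factory=AgatstonBlock)
    eval: EvalBlock = field(default_factory=EvalBlock)


def _build(cls, data: dict[str, Any], path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = dict(data)
    # recurse into nested dataclass blocks
    for f in dataclasses.fields(cls):
        if f.name in kwargs and dataclasses.is_dataclass(_default_of(f)):
            sub = kwargs[f.name]
            if not isinstance(sub, dict):
                raise ConfigError(f"{path}.{f.name} must be a mapping")
            kwargs[f.name] = _build(type(_default_of(f)), sub, f"{path}.{f.name}")
        elif f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def _default_of(f: dataclasses.Field):
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        return f.default_factory()  # type: ignore[misc]
    return f.default


def load_config(path: str | Path | None = None,
                data: dict[str, Any] | None = None) -> RunConfig:
    """Load a RunConfig from a YAML file or a raw mapping."""
    if data is None:
        if path is None:
            return RunConfig()
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return _build(RunConfig, data, "config")


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialize to YAML; load(dump(cfg)) == cfg."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    text = yaml.safe_dump(clean(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
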