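"""Pipeline configuration: one YAML-serializable record per run.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently running with defaults.  ``config_hash`` is embedded in every output
artifact so results can be traced back to the exact parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import PreprocessParams
from .segment import VesselnessParams
from .synth import SceneSpec


@dataclass
class StitchConfig:
    reference_index: int = 0
    reproj_tol_px: float = 2.0
    max_corners: int = 1500
    anms_n: int = 500
    ratio: float = 0.8


@dataclass
class MeasureConfig:
    erosion_r: int = 2
    median_k: int = 3
    dilation_r: int | None = None
    min_mask_area: int = 30
    model_source: str = "paper"     # "paper" or a JSON file path


@dataclass
class PipelineConfig:
    seed: int = 0
    roi: tuple[int, int, int, int] | None = None   # (x, y, w, h); None = auto
    synth: SceneSpec = field(default_factory=SceneSpec)
    stitch: StitchConfig = field(default_factory=StitchConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segment: VesselnessParams = field(default_factory=VesselnessParams)
    measure: MeasureConfig = field(default_factory=MeasureConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "synth", "stitch", "preprocess", "segment", "measure"):
            sub = {"synth": SceneSpec, "stitch": StitchConfig,
                   "preprocess": PreprocessParams, "segment": VesselnessParams,
                   "measure": MeasureConfig}[f.name]
            v = _build(sub, v, f"{path}.{f.name}")
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    return _build(PipelineConfig, data or {}, "config")


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
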