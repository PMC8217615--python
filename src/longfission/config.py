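"""Declarative run configuration: nested YAML blocks, schema-validated.

Unknown keys are rejected before any stage runs, so a typo in the YAML fails
fast instead of silently using a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SynthBlock(_Block):
    images_per_class: int = 100
    cells_per_image: tuple[int, int] = (3, 6)
    canvas: tuple[int, int] = (256, 256)
    background_noise_sd: float = 0.03
    background_level: float = 0.85
    invert: bool = False


class ExtractBlock(_Block):
    threshold: str | float = "otsu"
    connectivity: int = 8
    min_area: int = 50
    padding: int = 2

    @field_validator("threshold")
    @classmethod
    def _check_threshold(cls, v):
        if isinstance(v, str) and v != "otsu":
            raise ValueError("threshold must be 'otsu' or a float in (0,1)")
        return v


class SplitBlock(_Block):
    test_frac: float = 0.33
    val_frac_of_remainder: float = 0.2
    stratified: bool = True


class AugmentBlock(_Block):
    resize: tuple[int, int] = (128, 128)
    rotation_max_deg: float = 180.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    normalize_mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    normalize_std: tuple[float, float, float] = (0.5, 0.5, 0.5)


class ModelBlock(_Block):
    width_mult: float = 1.0
    num_classes: int = 2
    pretrained_path: str | None = None


class OptimBlock(_Block):
    lr: float = 0.001
    momentum: float = 0.9
    step_period: int = 7
    gamma: float = 0.1


class TrainBlock(_Block):
    epochs: int = 25
    batch_size: int = 16
    compensated_sums: bool = True


class RunConfig(_Block):
    """The pipeline's declarative form: one block per stage plus global seed."""

    synth: SynthBlock = SynthBlock()
    extract: ExtractBlock = ExtractBlock()
    split: SplitBlock = SplitBlock()
    augment: AugmentBlock = AugmentBlock()
    model: ModelBlock = ModelBlock()
    optim: OptimBlock = OptimBlock()
    train: TrainBlock = TrainBlock()
    seed: int = 0
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
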