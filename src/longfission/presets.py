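"""Canned run configurations.

``desk_scale_config`` is the CPU-scale study condition used throughout the
examples and verification runs: 200 synthetic images per class with 1-3
cells each, a quarter-width network, and 10 epochs.  The learning rate is
0.01 rather than the full-scale 0.001 because training starts from scratch
on a far smaller set (a few hundred updates in total), where the larger
step size is needed for the loss to traverse the same distance; every other
hyperparameter keeps its full-scale default.
"""

from __future__ import annotations

from .config import ModelBlock, OptimBlock, RunConfig, SynthBlock, TrainBlock


def desk_scale_config(
    seed: int,
    out_dir: str = "run",
    epochs: int = 10,
    pretrained_path: str | None = None,
    images_per_class: int = 200,
    width_mult: float = 0.25,
) -> RunConfig:
    """Desk-scale end-to-end condition (single CPU, minutes not hours)."""
    return RunConfig(
        synth=SynthBlock(images_per_class=images_per_class, cells_per_image=(1, 3)),
        model=ModelBlock(width_mult=width_mult, pretrained_path=pretrained_path),
        optim=OptimBlock(lr=0.01),
        train=TrainBlock(epochs=epochs),
        seed=seed,
        out_dir=out_dir,
    )
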