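"""Reproducible desk-scale experiments built from the pipeline pieces.

Two canned studies:

* :func:`end_to_end_run` — generate a synthetic dataset, extract, split,
  train the quarter-width classifier for 10 epochs and evaluate on the held
  -out test split, returning the headline metrics.
* :func:`transfer_comparison` — on a fixed dataset, fine-tune from a
  self-pretrained backbone vs. train from random initialization under
  otherwise identical conditions, and record the first epoch at which each
  reaches the 95% validation-accuracy threshold.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datasetprep import AugmentSpec
from .nn.resnet import NetworkSpec, build_network
from .pipeline import run_pipeline
from .presets import desk_scale_config
from .pretrain import self_pretrain
from .trainer import CropSet, TrainConfig, train

logger = logging.getLogger(__name__)

VAL_ACC_THRESHOLD = 95.0  # percent


def end_to_end_run(seed: int, out_dir: Path | str, epochs: int = 10) -> dict[str, float]:
    """One full synthetic pipeline run; returns test/validation metrics."""
    config = desk_scale_config(seed=seed, out_dir=str(out_dir), epochs=epochs)
    run_dir = run_pipeline(config)
    metrics = pd.read_csv(run_dir / "metrics.csv")
    history = pd.read_csv(run_dir / "history.csv")
    by_class = metrics.set_index("class")
    acc_row = by_class.loc["overall_accuracy"]
    return {
        "run_dir": str(run_dir),
        "test_accuracy_pct": float(acc_row["precision"]),  # stored in the first numeric column
        "best_val_accuracy_pct": float(history["val_acc"].max()),
        "longitudinal_precision_pct": float(by_class.loc["longitudinal_division", "precision"]),
        "longitudinal_recall_pct": float(by_class.loc["longitudinal_division", "recall"]),
        "longitudinal_f1_pct": float(by_class.loc["longitudinal_division", "f1"]),
        "other_precision_pct": float(by_class.loc["other_division", "precision"]),
        "other_recall_pct": float(by_class.loc["other_division", "recall"]),
        "other_f1_pct": float(by_class.loc["other_division", "f1"]),
        "n_test": int((pd.read_csv(run_dir / "manifest.csv")["split"] == "test").sum()),
    }


def first_epoch_at_threshold(
    run_dir: Path | str,
    seed: int,
    pretrained: str | None,
    threshold: float = VAL_ACC_THRESHOLD,
    max_epochs: int = 10,
    width_mult: float = 0.25,
) -> int:
    """First epoch whose validation accuracy reaches ``threshold`` (else max_epochs)."""
    run_dir = Path(run_dir)
    manifest = pd.read_csv(run_dir / "manifest.csv")
    train_set = CropSet.from_manifest(manifest, run_dir / "crops", "train")
    val_set = CropSet.from_manifest(manifest, run_dir / "crops", "val")
    net = build_network(NetworkSpec(width_mult=width_mult), rng=np.random.default_rng(seed))
    cfg = TrainConfig(
        epochs=max_epochs, lr=0.01, seed=seed, pretrained=pretrained, early_stop_val_acc=threshold
    )
    result = train(net, train_set, val_set, AugmentSpec(), cfg, rng=np.random.default_rng(seed))
    for rec in result.history:
        if rec.val_acc >= threshold:
            return rec.epoch
    return max_epochs


def transfer_comparison(
    dataset_run_dir: Path | str,
    checkpoint_dir: Path | str,
    seeds: tuple[int, ...],
    pretrain_seed: int,
) -> dict[str, float]:
    """Median first-epoch-to-threshold for pretrained vs. random initialization.

    The backbone checkpoint is produced once by self-pretraining on the
    auxiliary shape task; each comparison seed controls both arms' weight
    initialization, shuffling and augmentation, so the arms differ only in
    the starting weights.
    """
    ckpt = self_pretrain(Path(checkpoint_dir) / "pretrained.ckpt.npz", width_mult=0.25, seed=pretrain_seed)
    pre, rand = [], []
    for seed in seeds:
        pre.append(first_epoch_at_threshold(dataset_run_dir, seed, str(ckpt)))
        rand.append(first_epoch_at_threshold(dataset_run_dir, seed, None))
        logger.info("seed %d: pretrained@%d random@%d", seed, pre[-1], rand[-1])
    return {
        "epochs_to_95_pretrained": float(np.median(pre)),
        "epochs_to_95_random": float(np.median(rand)),
        "per_seed_pretrained": pre,
        "per_seed_random": rand,
    }
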