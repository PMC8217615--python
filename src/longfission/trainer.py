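"""Training loop: minibatch epochs, train/validation histories, best-model pick.

Hyperparameter defaults: 25 epochs, batches of
16, learning rate 0.001, momentum 0.9, learning-rate decay by 0.1 every 7
epochs.  The loss is two-class cross-entropy on the head scores.  Each epoch
runs one augmented training pass (weights updated per minibatch) and one
deterministic validation pass (resize + normalize only, no updates); the
weight snapshot with the highest validation accuracy — earliest epoch on
ties — is kept as the best model.

Epoch-level loss/accuracy sums go through the compensated accumulator when
``TrainConfig.compensated_sums`` is set (the default), which keeps the
averages stable even in single precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import evalmetrics
from .datasetprep import AugmentSpec, augment
from .extraction import load_png
from .nn.layers import softmax_cross_entropy
from .nn.resnet import ResNet, load_pretrained
from .optim import CompensatedAccumulator, LRSchedule, SGDState, kahan_add, lr_step, sgd_step

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 16
    lr: float = 0.001
    momentum: float = 0.9
    lr_period: int = 7
    lr_gamma: float = 0.1
    seed: int = 0
    pretrained: str | None = None
    compensated_sums: bool = True
    early_stop_val_acc: float | None = None  # stop once validation accuracy (%) reaches this

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_acc: float  # percent
    train_loss: float
    val_acc: float  # percent
    val_loss: float
    lr: float


@dataclass
class TrainResult:
    history: list[EpochRecord]
    best_val_accuracy: float
    best_epoch: int
    best_state: dict[str, np.ndarray]
    final_state: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


class CropSet:
    """In-memory split of crops (float32 grayscale in [0,1]) with labels."""

    def __init__(self, images: Sequence[np.ndarray], labels: Sequence[int]):
        if len(images) != len(labels):
            raise ValueError("images/labels length mismatch")
        self.images = list(images)
        self.labels = np.asarray(labels, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.images)

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame, root: Path | str, split: str | None = None) -> "CropSet":
        df = manifest if split is None else manifest[manifest["split"] == split]
        root = Path(root)
        return cls([load_png(root / p) for p in df["path"]], df["class_id"].to_numpy())


def minibatch_iter(n_items: int, batch_size: int, rng: np.random.Generator) -> Iterator[np.ndarray]:
    """Sampling without replacement: every index appears exactly once per epoch.

    The final batch may be smaller; a batch size above the set size yields a
    single full batch with a warning.
    """
    if n_items < 1:
        raise ValueError("empty split")
    if batch_size > n_items:
        logger.warning("batch_size %d > set size %d; using one batch", batch_size, n_items)
    perm = rng.permutation(n_items)
    for start in range(0, n_items, batch_size):
        yield perm[start : start + batch_size]


def _mean(total: float, n: int) -> float:
    return total / n if n else float("nan")


class _Sum:
    """Plain or compensated scalar accumulator behind one interface."""

    def __init__(self, compensated: bool):
        self._acc = CompensatedAccumulator(dtype=np.float32) if compensated else None
        self._plain = 0.0

    def add(self, x: float) -> None:
        if self._acc is not None:
            kahan_add(self._acc, x)
        else:
            self._plain += x

    @property
    def value(self) -> float:
        return float(self._acc.s) if self._acc is not None else self._plain


def evaluate_pass(
    network: ResNet, data: CropSet, spec: AugmentSpec, batch_size: int = 64, compensated: bool = True
) -> tuple[float, float, np.ndarray]:
    """Deterministic eval pass: (accuracy %, mean loss, predictions)."""
    preds = np.empty(len(data), dtype=np.int64)
    loss_sum = _Sum(compensated)
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        x = np.stack([augment(data.images[i], spec, training=False) for i in idx])
        logits = network.forward(x, training=False)
        loss, _ = softmax_cross_entropy(logits, data.labels[idx])
        loss_sum.add(loss * len(idx))
        preds[idx] = logits.argmax(axis=1)
    cm = evalmetrics.confusion(preds, data.labels)
    return evalmetrics.accuracy(cm), _mean(loss_sum.value, len(data)), preds


def train(
    network: ResNet,
    train_set: CropSet,
    val_set: CropSet,
    augment_spec: AugmentSpec,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> TrainResult:
    """Fit the network; see the module docstring for the loop contract."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation splits must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.pretrained:
        load_pretrained(network, config.pretrained)
        logger.info("initialized body from pretrained checkpoint %s", config.pretrained)
    schedule = LRSchedule(period=config.lr_period, gamma=config.lr_gamma)
    state = SGDState(network.parameters(), lr=config.lr, momentum=config.momentum)
    history: list[EpochRecord] = []
    best_acc, best_epoch, best_state = -1.0, -1, network.state_dict()
    for epoch in range(config.epochs):
        state.lr = lr_step(schedule, epoch, config.lr)
        loss_sum = _Sum(config.compensated_sums)
        train_preds = np.empty(len(train_set), dtype=np.int64)
        for batch in minibatch_iter(len(train_set), config.batch_size, rng):
            x = np.stack([augment(train_set.images[i], augment_spec, rng, training=True) for i in batch])
            y = train_set.labels[batch]
            logits = network.forward(x, training=True)
            loss, dlogits = softmax_cross_entropy(logits, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (lr={state.lr:g}); logits range "
                    f"[{np.nanmin(logits):g}, {np.nanmax(logits):g}]"
                )
            network.backward(dlogits)
            sgd_step(state, network.gradients())
            loss_sum.add(loss * len(batch))
            train_preds[batch] = logits.argmax(axis=1)
        train_cm = evalmetrics.confusion(train_preds, train_set.labels)
        train_acc = evalmetrics.accuracy(train_cm)
        val_acc, val_loss, _ = evaluate_pass(
            network, val_set, augment_spec, compensated=config.compensated_sums
        )
        rec = EpochRecord(epoch, train_acc, _mean(loss_sum.value, len(train_set)), val_acc, val_loss, state.lr)
        history.append(rec)
        logger.info(
            "epoch %d: train acc %.2f%% loss %.4f | val acc %.2f%% loss %.4f | lr %g",
            epoch, rec.train_acc, rec.train_loss, rec.val_acc, rec.val_loss, rec.lr,
        )
        if val_acc > best_acc:
            best_acc, best_epoch, best_state = val_acc, epoch, network.state_dict()
        if config.early_stop_val_acc is not None and val_acc >= config.early_stop_val_acc:
            logger.info("early stop: val acc %.2f%% reached threshold at epoch %d", val_acc, epoch)
            break
    return TrainResult(history, best_acc, best_epoch, best_state, network.state_dict())


def predict(
    network: ResNet, images: Sequence[np.ndarray], spec: AugmentSpec, batch_size: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic class ids + raw scores, order-preserving.

    The class id is the index of the maximal score; on an exact tie the
    lower index wins.
    """
    preds = np.empty(len(images), dtype=np.int64)
    scores = np.empty((len(images), network.spec.num_classes), dtype=np.float32)
    for start in range(0, len(images), batch_size):
        chunk = images[start : start + batch_size]
        x = np.stack([augment(im, spec, training=False) for im in chunk])
        logits = network.forward(x, training=False)
        scores[start : start + len(chunk)] = logits
        preds[start : start + len(chunk)] = logits.argmax(axis=1)
    return preds, scores


def save_history(history: Sequence[EpochRecord], path: Path | str) -> None:
    pd.DataFrame(
        [
            {
                "epoch": r.epoch,
                "train_acc": r.train_acc,
                "train_loss": r.train_loss,
                "val_acc": r.val_acc,
                "val_loss": r.val_loss,
                "lr": r.lr,
            }
            for r in history
        ]
    ).to_csv(path, index=False)
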