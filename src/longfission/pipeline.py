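"""End-to-end orchestration: synth -> extract -> split -> train -> evaluate.

Each stage writes its artifacts under the run directory and appends to a run
manifest (config hash, seed, produced files), so a run directory is
self-describing and reproducible from its config + seed alone.  Stage seeds
are fanned out deterministically from the global seed, so a stage can be
re-run independently without disturbing the others.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evalmetrics
from .config import RunConfig
from .datasetprep import AugmentSpec, SplitSpec, assign_splits, build_manifest
from .extraction import ExtractionConfig, extract_crops, extract_image, load_png, pad_box
from .nn.resnet import NetworkSpec, build_network, load_checkpoint, save_checkpoint
from .synthgen import SynthConfig, generate_dataset
from .trainer import CropSet, TrainConfig, predict, save_history, train

logger = logging.getLogger(__name__)

STAGES = ("synth", "extract", "split", "train", "evaluate")


def _stage_seed(global_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    child = np.random.SeedSequence(global_seed).spawn(len(STAGES))[idx]
    return int(child.generate_state(1)[0] % (2**31))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage '{needed_by}' needs {path}; run stage '{stage}' first")
    return path


def run_synth(config: RunConfig, run_dir: Path) -> Path:
    synth_cfg = SynthConfig(
        images_per_class=config.synth.images_per_class,
        cells_per_image=config.synth.cells_per_image,
        canvas=config.synth.canvas,
        background_noise_sd=config.synth.background_noise_sd,
        background_level=config.synth.background_level,
        invert=config.synth.invert,
        seed=_stage_seed(config.seed, "synth"),
    )
    out = run_dir / "synth"
    generate_dataset(synth_cfg, out)
    logger.info("synth: wrote %d images per class under %s", synth_cfg.images_per_class, out)
    return out


def run_extract(config: RunConfig, run_dir: Path, in_dir: Path | None = None) -> Path:
    src = in_dir or _require(run_dir / "synth", "synth", "extract")
    ex_cfg = ExtractionConfig(
        threshold=config.extract.threshold,
        connectivity=config.extract.connectivity,
        min_area=config.extract.min_area,
        invert=config.synth.invert,
    )
    out = run_dir / "crops"
    rows = []
    for cls_dir in sorted(d for d in Path(src).iterdir() if d.is_dir()):
        class_id = {"longitudinal_division": 0, "other_division": 1}.get(cls_dir.name)
        if class_id is None:
            continue
        for img_path in sorted(cls_dir.glob("*.png")):
            image = load_png(img_path)
            boxes = extract_image(image, ex_cfg, padding=config.extract.padding)
            crop_paths = extract_crops(
                image,
                [b for b, _ in boxes],
                out / cls_dir.name,
                padding=config.extract.padding,
                src_name=img_path.stem,
            )
            for (box, _area), cp in zip(boxes, crop_paths):
                rows.append(
                    {
                        "path": str(cp.relative_to(out)),
                        "class_id": class_id,
                        "src_image": f"{cls_dir.name}/{img_path.name}",
                        "row0": box.row0,
                        "col0": box.col0,
                        "row1": box.row1,
                        "col1": box.col1,
                    }
                )
    manifest = pd.DataFrame(rows, columns=["path", "class_id", "src_image", "row0", "col0", "row1", "col1"])
    manifest.to_csv(out / "manifest.csv", index=False)
    logger.info("extract: %d crops -> %s", len(manifest), out)
    return out


def run_split(config: RunConfig, run_dir: Path) -> Path:
    crops = _require(run_dir / "crops", "extract", "split")
    manifest = build_manifest(crops)
    spec = SplitSpec(
        test_frac=config.split.test_frac,
        val_frac_of_remainder=config.split.val_frac_of_remainder,
        stratified=config.split.stratified,
        seed=_stage_seed(config.seed, "split"),
    )
    out = run_dir / "manifest.csv"
    assign_splits(manifest, spec).to_csv(out, index=False)
    logger.info("split: wrote %s", out)
    return out


def _augment_spec(config: RunConfig) -> AugmentSpec:
    a = config.augment
    return AugmentSpec(
        resize=a.resize,
        rotation_max_deg=a.rotation_max_deg,
        hflip_prob=a.hflip_prob,
        vflip_prob=a.vflip_prob,
        normalize_mean=a.normalize_mean,
        normalize_std=a.normalize_std,
    )


def run_train(config: RunConfig, run_dir: Path) -> Path:
    manifest_path = _require(run_dir / "manifest.csv", "split", "train")
    manifest = pd.read_csv(manifest_path)
    seed = _stage_seed(config.seed, "train")
    net = build_network(
        NetworkSpec(width_mult=config.model.width_mult, num_classes=config.model.num_classes),
        rng=np.random.default_rng(seed),
    )
    cfg = TrainConfig(
        epochs=config.train.epochs,
        batch_size=config.train.batch_size,
        lr=config.optim.lr,
        momentum=config.optim.momentum,
        lr_period=config.optim.step_period,
        lr_gamma=config.optim.gamma,
        seed=seed,
        pretrained=config.model.pretrained_path,
        compensated_sums=config.train.compensated_sums,
    )
    crops_root = run_dir / "crops"
    train_set = CropSet.from_manifest(manifest, crops_root, "train")
    val_set = CropSet.from_manifest(manifest, crops_root, "val")
    result = train(net, train_set, val_set, _augment_spec(config), cfg, rng=np.random.default_rng(seed))
    save_history(result.history, run_dir / "history.csv")
    net.load_state_dict(result.best_state)
    ckpt = run_dir / "best.ckpt.npz"
    save_checkpoint(net, ckpt)
    logger.info(
        "train: best val acc %.4f%% at epoch %d -> %s", result.best_val_accuracy, result.best_epoch, ckpt
    )
    return ckpt


def network_from_checkpoint(path: Path | str, num_classes: int = 2):
    """Rebuild a network whose width is inferred from the checkpoint's head."""
    state = load_checkpoint(path)
    width_mult = state["fc.weight"].shape[1] / 512.0
    net = build_network(NetworkSpec(width_mult=width_mult, num_classes=state["fc.weight"].shape[0]))
    net.load_state_dict(state)
    return net


def run_evaluate(config: RunConfig, run_dir: Path) -> evalmetrics.MetricsReport:
    ckpt = _require(run_dir / "best.ckpt.npz", "train", "evaluate")
    manifest = pd.read_csv(_require(run_dir / "manifest.csv", "split", "evaluate"))
    net = network_from_checkpoint(ckpt)
    test_set = CropSet.from_manifest(manifest, run_dir / "crops", "test")
    preds, _scores = predict(net, test_set.images, _augment_spec(config))
    cm = evalmetrics.confusion(preds, test_set.labels)
    rep = evalmetrics.report(cm)
    pd.DataFrame(cm.counts, index=["true_0", "true_1"], columns=["pred_0", "pred_1"]).to_csv(
        run_dir / "confusion.csv"
    )
    evalmetrics.report_to_csv(rep, run_dir / "metrics.csv")
    logger.info("evaluate: test accuracy %.4f%%", rep.accuracy)
    return rep


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None, run_dir: Path | str | None = None):
    """Execute the requested stages in pipeline order; returns the run directory.

    The run manifest ``run.json`` records the config (and its hash), the
    global seed, and each stage's artifacts.
    """
    stages = tuple(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    run_dir = Path(run_dir or config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(run_dir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("longfission")
    root.addHandler(log_handler)
    artifacts: dict[str, str] = {}
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            logger.info("--- stage %s ---", stage)
            if stage == "synth":
                artifacts["synth"] = str(run_synth(config, run_dir))
            elif stage == "extract":
                artifacts["extract"] = str(run_extract(config, run_dir))
            elif stage == "split":
                artifacts["split"] = str(run_split(config, run_dir))
            elif stage == "train":
                artifacts["train"] = str(run_train(config, run_dir))
            elif stage == "evaluate":
                rep = run_evaluate(config, run_dir)
                artifacts["evaluate"] = str(run_dir / "metrics.csv")
                artifacts["test_accuracy_pct"] = f"{rep.accuracy:.4f}"
        manifest = {
            "config": config.model_dump(mode="json"),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": list(stages),
            "artifacts": artifacts,
        }
        with open(run_dir / "run.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    return run_dir
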