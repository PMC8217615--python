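"""Synthetic phase-contrast microscope images with known per-cell ground truth.

Cells are rendered as dark capsules (rounded-end rods) on a light noisy
background, following the phase-contrast convention.  Two morphology classes
are emulated:

* class 0, ``longitudinal_division`` — cells dividing along the long axis,
  so they are wide relative to their length (width/length sampled above
  0.55) and carry a darker septum line *along* the major axis;
* class 1, ``other_division`` — plain rods (width/length below 0.45), some
  with a transverse septum, plus adversarial negatives bearing a very
  narrow transverse crease (a thin indentation that tempts a classifier
  toward the longitudinal class).

Every placed cell is recorded with its tight bounding box and class id, so
extraction, splitting, training and evaluation are all testable without any
external data.  Identical configuration + seed reproduce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evalmetrics import CLASS_NAMES
from .extraction import BoundingBox, save_png

SEPTUM_KINDS = ("longitudinal", "transverse", "none")


@dataclass(frozen=True)
class CellSpec:
    """Geometry and intensity of one rendered cell.

    ``length``/``width`` are the capsule's major/minor extents in pixels,
    ``orientation`` the major-axis angle in [0, pi), ``septum`` the kind of
    division line drawn, ``crease_width`` the width (px) of a thin transverse
    indentation (0 = none), ``intensity`` the foreground gray level in [0,1].
    """

    center: tuple[float, float]  # (row, col)
    length: float
    width: float
    orientation: float
    septum: str = "none"
    crease_width: float = 0.0
    intensity: float = 0.25

    def __post_init__(self) -> None:
        if not (self.length >= self.width >= 3.0):
            raise ValueError("need length >= width >= 3 px")
        if not 0.0 <= self.orientation < np.pi:
            raise ValueError("orientation must lie in [0, pi)")
        if self.septum not in SEPTUM_KINDS:
            raise ValueError(f"septum must be one of {SEPTUM_KINDS}")
        if not 0.0 <= self.crease_width < self.width:
            raise ValueError("crease_width must be >= 0 and < width")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")


@dataclass(frozen=True)
class ClassGeometry:
    """Sampling ranges for one class's CellSpec fields."""

    length_range: tuple[float, float] = (24.0, 40.0)
    width_to_length: tuple[float, float] = (0.2, 0.45)
    intensity_range: tuple[float, float] = (0.15, 0.35)
    septum_probs: dict[str, float] = field(
        default_factory=lambda: {"longitudinal": 0.0, "transverse": 0.5, "none": 0.5}
    )
    crease_prob: float = 0.0
    crease_width_range: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.length_range, self.width_to_length, self.intensity_range, self.crease_width_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError("distribution bounds must be finite and ordered")
        if abs(sum(self.septum_probs.values()) - 1.0) > 1e-9:
            raise ValueError("septum probabilities must sum to 1")


def default_class_geometry() -> dict[int, ClassGeometry]:
    """Wide cells with an axial septum vs. plain/transverse rods (some creased)."""
    return {
        0: ClassGeometry(
            width_to_length=(0.55, 0.80),
            septum_probs={"longitudinal": 1.0, "transverse": 0.0, "none": 0.0},
        ),
        1: ClassGeometry(
            width_to_length=(0.20, 0.45),
            septum_probs={"longitudinal": 0.0, "transverse": 0.5, "none": 0.5},
            crease_prob=0.25,
        ),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    images_per_class: int = 100
    cells_per_image: tuple[int, int] = (3, 6)
    canvas: tuple[int, int] = (256, 256)
    background_noise_sd: float = 0.03
    background_level: float = 0.85
    class_geometry: dict[int, ClassGeometry] = field(default_factory=default_class_geometry)
    seed: int = 0
    invert: bool = False
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.canvas[0] < 64 or self.canvas[1] < 64:
            raise ValueError("canvas dims must be >= 64")
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if not 0 < self.cells_per_image[0] <= self.cells_per_image[1]:
            raise ValueError("cells_per_image range must be positive and ordered")
        if self.background_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class GroundTruthCell:
    box: BoundingBox
    class_id: int
    spec: CellSpec


@dataclass(frozen=True)
class GroundTruth:
    """Per-cell boxes + class ids for one image (0=longitudinal, 1=other)."""

    cells: tuple[GroundTruthCell, ...]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        for c in self.cells:
            if c.class_id not in (0, 1):
                raise ValueError("class id must be 0 or 1")
            if c.box.row0 < 0 or c.box.col0 < 0 or c.box.row1 > self.shape[0] or c.box.col1 > self.shape[1]:
                raise ValueError("ground-truth box outside canvas")


# ---------------------------------------------------------------- rendering


def _cell_coords(shape: tuple[int, int], spec: CellSpec) -> tuple[np.ndarray, np.ndarray]:
    """Axial/perpendicular coordinates of every pixel relative to the cell axis."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - spec.center[0]
    dc = cc - spec.center[1]
    ct, st = np.cos(spec.orientation), np.sin(spec.orientation)
    axial = dc * ct + dr * st
    perp = -dc * st + dr * ct
    return axial, perp


def cell_mask(shape: tuple[int, int], spec: CellSpec) -> np.ndarray:
    """Boolean mask of the capsule with any crease notches removed."""
    axial, perp = _cell_coords(shape, spec)
    half_seg = max(spec.length - spec.width, 0.0) / 2.0
    t = np.clip(axial, -half_seg, half_seg)
    dist = np.hypot(axial - t, perp)
    mask = dist <= spec.width / 2.0
    if spec.crease_width > 0:
        depth = 0.35 * spec.width
        notch = (np.abs(axial) <= spec.crease_width / 2.0) & (np.abs(perp) >= spec.width / 2.0 - depth)
        mask &= ~notch
    return mask


def _cell_extent(spec: CellSpec) -> tuple[float, float]:
    half_seg = max(spec.length - spec.width, 0.0) / 2.0
    ct, st = abs(np.cos(spec.orientation)), abs(np.sin(spec.orientation))
    return half_seg * st + spec.width / 2.0, half_seg * ct + spec.width / 2.0  # (rows, cols)


def render_cell(canvas: np.ndarray, spec: CellSpec, invert: bool = False) -> np.ndarray:
    """Paint one cell onto a copy of ``canvas`` and return it.

    The body takes ``spec.intensity``; a septum is drawn as a darker contrast
    line (along the major axis for longitudinal, across it for transverse);
    a crease removes thin notches at the cell edge.  ``invert`` renders
    bright-on-dark instead.  Raises if the cell does not fit in the canvas.
    """
    canvas = np.asarray(canvas, dtype=np.float32).copy()
    er, ec = _cell_extent(spec)
    r, c = spec.center
    if r - er < 0 or c - ec < 0 or r + er > canvas.shape[0] - 1 or c + ec > canvas.shape[1] - 1:
        raise ValueError(f"cell at {spec.center} (extent {er:.1f}x{ec:.1f}) does not fit in {canvas.shape}")
    mask = cell_mask(canvas.shape, spec)
    body = spec.intensity if not invert else 1.0 - spec.intensity
    canvas[mask] = body
    axial, perp = _cell_coords(canvas.shape, spec)
    half_seg = max(spec.length - spec.width, 0.0) / 2.0
    septum_level = spec.intensity * 0.45 if not invert else 1.0 - spec.intensity * 0.45
    if spec.septum == "longitudinal":
        half_t = max(0.06 * spec.width, 0.75)
        line = mask & (np.abs(perp) <= half_t) & (np.abs(axial) <= max(half_seg, spec.length * 0.3))
        canvas[line] = septum_level
    elif spec.septum == "transverse":
        half_t = max(0.06 * spec.width, 0.75)
        line = mask & (np.abs(axial) <= half_t)
        canvas[line] = septum_level
    return canvas


def _mask_bbox(mask: np.ndarray) -> BoundingBox:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


# ---------------------------------------------------------------- sampling


def _sample_spec(geom: ClassGeometry, config: SynthConfig, rng: np.random.Generator) -> CellSpec:
    length = rng.uniform(*geom.length_range)
    width = max(3.0, length * rng.uniform(*geom.width_to_length))
    orientation = rng.uniform(0.0, np.pi)
    kinds = list(geom.septum_probs)
    septum = kinds[rng.choice(len(kinds), p=[geom.septum_probs[k] for k in kinds])]
    crease = 0.0
    if geom.crease_prob > 0 and rng.random() < geom.crease_prob:
        crease = min(rng.uniform(*geom.crease_width_range), width - 1.0)
    intensity = rng.uniform(*geom.intensity_range)
    # center sampled so the rotated capsule fits with a 2 px margin
    probe = CellSpec((0.0, 0.0), length, width, orientation, septum, crease, intensity)
    er, ec = _cell_extent(probe)
    h, w = config.canvas
    if 2 * er + 4 >= h or 2 * ec + 4 >= w:
        raise ValueError("cell larger than canvas margin allows")
    center = (rng.uniform(er + 2, h - 1 - er - 2), rng.uniform(ec + 2, w - 1 - ec - 2))
    return replace(probe, center=center)


def generate_microscope_image(
    config: SynthConfig, rng: np.random.Generator, class_id: int = 0
) -> tuple[np.ndarray, GroundTruth]:
    """One single-class colony image plus its ground truth.

    Cells are placed by rejection sampling so their (2 px inflated) boxes do
    not overlap — touching cells would be merged by extraction and corrupt
    the labels.  Gaussian background noise with the configured sd is added
    last; ground-truth boxes come from the noise-free masks.
    """
    geom = config.class_geometry[class_id]
    h, w = config.canvas
    bg = config.background_level if not config.invert else 1.0 - config.background_level
    canvas = np.full((h, w), bg, dtype=np.float32)
    n_cells = int(rng.integers(config.cells_per_image[0], config.cells_per_image[1] + 1))
    placed: list[GroundTruthCell] = []
    taken: list[BoundingBox] = []
    for _ in range(n_cells):
        for attempt in range(config.max_retries):
            spec = _sample_spec(geom, config, rng)
            mask = cell_mask((h, w), spec)
            box = _mask_bbox(mask)
            inflated = BoundingBox(
                max(0, box.row0 - 2), max(0, box.col0 - 2), min(h, box.row1 + 2), min(w, box.col1 + 2)
            )
            if all(inflated.iou(t) == 0.0 for t in taken):
                canvas = render_cell(canvas, spec, invert=config.invert)
                placed.append(GroundTruthCell(box, class_id, spec))
                taken.append(inflated)
                break
        else:
            raise RuntimeError(
                f"could not place cell {len(placed) + 1}/{n_cells} after {config.max_retries} retries "
                f"(canvas {config.canvas}, cells_per_image {config.cells_per_image})"
            )
    if config.background_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.background_noise_sd, canvas.shape).astype(np.float32)
    canvas = np.clip(canvas, 0.0, 1.0).astype(np.float32)
    return canvas, GroundTruth(tuple(placed), (h, w))


def generate_dataset(config: SynthConfig, out_dir: Path | str) -> pd.DataFrame:
    """Write one folder of PNGs per class plus CSV manifests; return the manifest.

    ``manifest.csv`` lists every image (`path,class_id,src_image,row0,col0,
    row1,col1`; box fields are empty for whole images); ``cells.csv`` lists
    every planted cell with its ground-truth box.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    cell_rows: list[dict] = []
    for class_id in (0, 1):
        cls_dir = out_dir / CLASS_NAMES[class_id]
        cls_dir.mkdir(exist_ok=True)
        for i in range(config.images_per_class):
            image, gt = generate_microscope_image(config, rng, class_id=class_id)
            rel = f"{CLASS_NAMES[class_id]}/img{i:04d}.png"
            save_png(image, out_dir / rel)
            rows.append(
                {"path": rel, "class_id": class_id, "src_image": "", "row0": "", "col0": "", "row1": "", "col1": ""}
            )
            for cell in gt.cells:
                cell_rows.append(
                    {
                        "src_image": rel,
                        "class_id": class_id,
                        "row0": cell.box.row0,
                        "col0": cell.box.col0,
                        "row1": cell.box.row1,
                        "col1": cell.box.col1,
                    }
                )
    manifest = pd.DataFrame(rows, columns=["path", "class_id", "src_image", "row0", "col0", "row1", "col1"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(cell_rows).to_csv(out_dir / "cells.csv", index=False)
    return manifest
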