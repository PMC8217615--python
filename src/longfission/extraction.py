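"""Single-cell extraction from microscope images.

The pre-processing pipeline: binarize each grayscale image (cells are dark on
a light phase-contrast background), label contiguous foreground groups —
each group representing one bacterium — drop groups smaller than an a-priori
area threshold, take the tight bounding box of each survivor, and export the
original-intensity crop of every box as a PNG.

Coordinates are 0-based and half-open: a box covers rows [row0, row1) and
columns [col0, col1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.measure import regionprops


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"degenerate box {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    def area(self) -> int:
        return self.height * self.width

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union of two boxes."""
        ri = max(0, min(self.row1, other.row1) - max(self.row0, other.row0))
        ci = max(0, min(self.col1, other.col1) - max(self.col0, other.col0))
        inter = ri * ci
        union = self.area() + other.area() - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class ExtractionConfig:
    """Binarization + grouping settings.

    ``threshold``: "otsu" (from the image's own histogram) or a fixed value
    in (0, 1).  ``connectivity``: 4 or 8 neighbors.  ``min_area``: groups
    with fewer pixels are ignored.  ``invert``: treat bright pixels as
    foreground instead of dark ones.
    """

    threshold: str | float = "otsu"
    connectivity: int = 8
    min_area: int = 50
    invert: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str):
            if self.threshold != "otsu":
                raise ValueError("threshold must be 'otsu' or a float in (0,1)")
        elif not 0.0 < float(self.threshold) < 1.0:
            raise ValueError("fixed threshold must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")


@dataclass(frozen=True)
class ComponentLabeling:
    """Integer raster: 0 = background, ids 1..count in raster-scan order of first pixel."""

    labels: np.ndarray
    count: int


def binarize(image: np.ndarray, config: ExtractionConfig = ExtractionConfig()) -> np.ndarray:
    """Boolean foreground mask: pixels darker than the threshold (brighter if invert)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or not np.all(np.isfinite(img)):
        raise ValueError("image must be 2-D with finite intensities")
    if config.threshold == "otsu":
        if np.ptp(img) == 0:
            raise ValueError(
                "constant image: Otsu threshold is undefined; use a fixed threshold instead"
            )
        thr = threshold_otsu(img)
    else:
        thr = float(config.threshold)
    return (img > thr) if config.invert else (img < thr)


def label_components(binary: np.ndarray, connectivity: int = 8) -> ComponentLabeling:
    """Group contiguous foreground pixels; ids follow raster-scan order of first pixel."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    raw = _sk_label(np.asarray(binary, dtype=bool), connectivity=1 if connectivity == 4 else 2)
    n = int(raw.max())
    if n == 0:
        return ComponentLabeling(np.zeros_like(raw), 0)
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first occurrence per label id
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return ComponentLabeling(remap[raw], n)


def bounding_boxes(labeling: ComponentLabeling, min_area: int = 50) -> list[tuple[BoundingBox, int]]:
    """Tight box + pixel area per component with area >= min_area, ordered by id."""
    out: list[tuple[BoundingBox, int]] = []
    for prop in sorted(regionprops(labeling.labels), key=lambda p: p.label):
        if prop.area >= min_area:
            r0, c0, r1, c1 = prop.bbox
            out.append((BoundingBox(int(r0), int(c0), int(r1), int(c1)), int(prop.area)))
    return out


def pad_box(box: BoundingBox, padding: int, shape: tuple[int, int]) -> BoundingBox:
    """Inflate a box by ``padding`` pixels, clipped to the image bounds."""
    return BoundingBox(
        max(0, box.row0 - padding),
        max(0, box.col0 - padding),
        min(shape[0], box.row1 + padding),
        min(shape[1], box.col1 + padding),
    )


def extract_crops(
    image: np.ndarray,
    boxes: Sequence[BoundingBox],
    out_dir: Path | str,
    padding: int = 2,
    src_name: str = "image",
) -> list[Path]:
    """Write one original-intensity PNG per (padded, clipped) box.

    Filenames are ``{src_name}_cell{index:03d}.png``; intensities are the
    source grayscale values, not the binary mask.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = np.asarray(image, dtype=np.float64)
    paths: list[Path] = []
    for i, box in enumerate(boxes):
        b = pad_box(box, padding, img.shape)
        crop = img[b.row0 : b.row1, b.col0 : b.col1]
        path = out_dir / f"{src_name}_cell{i:03d}.png"
        save_png(crop, path)
        paths.append(path)
    return paths


def save_png(image: np.ndarray, path: Path | str) -> None:
    """Save a float [0,1] (or uint8) grayscale raster as an 8-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def load_png(path: Path | str) -> np.ndarray:
    """Load an image as float32 grayscale in [0, 1] (color inputs are averaged)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L" if im.mode not in ("I;16", "I") else im.mode))
    arr = arr.astype(np.float32)
    scale = 65535.0 if arr.max() > 255 else 255.0
    return arr / scale


def extract_image(
    image: np.ndarray,
    config: ExtractionConfig = ExtractionConfig(),
    padding: int = 2,
) -> list[tuple[BoundingBox, int]]:
    """Convenience composition: binarize -> label -> filtered bounding boxes."""
    binary = binarize(image, config)
    labeling = label_components(binary, config.connectivity)
    return bounding_boxes(labeling, config.min_area)
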