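"""Dataset partitioning and load-time augmentation.

Splitting holds out 33% of each class for testing, then 20% of the remainder
for validation, with ceiling rounding on the held-out counts — the
convention that yields the reference per-class subset sizes exactly
(e.g. 2,244 -> 1,202/301/741 and 12,846 -> 6,884/1,722/4,240).  Sizes are
seed-independent; membership is randomized by the seed.

Augmentation (training mode) is resize to 128x128, a uniform random rotation
in [-180, 180] degrees, then independent horizontal/vertical flips, then
per-channel normalization; evaluation mode applies only resize + normalize
so reported metrics are deterministic.  Grayscale crops are replicated to
three channels to satisfy the classifier's input stem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out fractions: test from the whole, validation from the remainder."""

    test_frac: float = 0.33
    val_frac_of_remainder: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_frac < 1.0 or not 0.0 < self.val_frac_of_remainder < 1.0:
            raise ValueError("fractions must lie in (0, 1)")


def split_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """(train, val, test) sizes under the ceiling convention."""
    n_test = ceil(n * spec.test_frac)
    n_val = ceil((n - n_test) * spec.val_frac_of_remainder)
    n_train = n - n_test - n_val
    return n_train, n_val, n_test


def split_class(
    items, spec: SplitSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint exhaustive (train, val, test) index sets for one class.

    ``items`` is a count or a sequence (split by position).  Raises if any
    subset would be empty.
    """
    n = items if isinstance(items, (int, np.integer)) else len(items)
    if n < 3:
        raise ValueError("need at least 3 items to form three subsets")
    n_train, n_val, n_test = split_sizes(n, spec)
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"empty subset for n={n} with fractions {spec.test_frac}/{spec.val_frac_of_remainder}")
    perm = rng.permutation(n)
    test = np.sort(perm[:n_test])
    val = np.sort(perm[n_test : n_test + n_val])
    train = np.sort(perm[n_test + n_val :])
    return train, val, test


def assign_splits(manifest: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Add a ``split`` column (train/val/test), per class when stratified."""
    out = manifest.copy()
    out["split"] = ""
    rng = np.random.default_rng(spec.seed)
    groups = out.groupby("class_id").indices if spec.stratified else {0: np.arange(len(out))}
    for _, idx in sorted(groups.items()):
        tr, va, te = split_class(len(idx), spec, rng)
        out.iloc[idx[tr], out.columns.get_loc("split")] = "train"
        out.iloc[idx[va], out.columns.get_loc("split")] = "val"
        out.iloc[idx[te], out.columns.get_loc("split")] = "test"
    return out


def build_manifest(root: Path | str) -> pd.DataFrame:
    """List every image under class-named subfolders of ``root``.

    Class ids follow lexicographic folder-name order, so
    ``longitudinal_division`` -> 0 and ``other_division`` -> 1.  Non-image
    files are skipped with a warning.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"need at least 2 class folders under {root}, found {len(class_dirs)}")
    rows = []
    for class_id, d in enumerate(class_dirs):
        files = sorted(d.iterdir())
        images = [f for f in files if f.suffix.lower() in IMAGE_SUFFIXES]
        for f in files:
            if f.is_file() and f.suffix.lower() not in IMAGE_SUFFIXES:
                logger.warning("skipping non-image file %s", f)
        if not images:
            raise ValueError(f"class folder {d} contains no images")
        rows += [{"path": str(f.relative_to(root)), "class_id": class_id} for f in images]
    return pd.DataFrame(rows, columns=["path", "class_id"])


@dataclass(frozen=True)
class AugmentSpec:
    """Resize / rotation / flip / normalization settings.

    Normalization defaults to mean 0.5, std 0.5 per channel; when fine-tuning
    from externally pretrained weights the conventional channel constants of
    that checkpoint should be supplied instead.
    """

    resize: tuple[int, int] = (128, 128)
    rotation_max_deg: float = 180.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    normalize_mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    normalize_std: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.resize[0] < 1 or self.resize[1] < 1:
            raise ValueError("resize dims must be positive")
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if any(s <= 0 for s in self.normalize_std):
            raise ValueError("normalize_std must be positive")


def resize_gray(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a 2-D float image (anti-aliased when shrinking)."""
    return _sk_resize(
        image.astype(np.float64), shape, order=1, anti_aliasing=None, preserve_range=True
    ).astype(np.float32)


def augment(
    image: np.ndarray,
    spec: AugmentSpec,
    rng: np.random.Generator | None = None,
    training: bool = True,
) -> np.ndarray:
    """One crop -> normalized (3, H, W) float32 tensor.

    Training mode: resize -> random rotation (empty corners filled with the
    image median) -> random flips -> normalize.  Eval mode: resize ->
    normalize only.  Accepts 2-D grayscale or (H, W, 3) input; grayscale is
    replicated to 3 channels before normalization.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[2] == 3:
        img = img.mean(axis=2)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected non-empty 2-D or (H,W,3) image, got shape {img.shape}")
    img = resize_gray(img, spec.resize)
    if training:
        if rng is None:
            raise ValueError("training-mode augmentation needs an rng")
        if spec.rotation_max_deg > 0:
            angle = rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg)
            img = _sk_rotate(
                img, angle, resize=False, order=1, mode="constant", cval=float(np.median(img)), preserve_range=True
            ).astype(np.float32)
        if spec.hflip_prob > 0 and rng.random() < spec.hflip_prob:
            img = img[:, ::-1]
        if spec.vflip_prob > 0 and rng.random() < spec.vflip_prob:
            img = img[::-1, :]
    chw = np.repeat(img[None], 3, axis=0)
    mean = np.asarray(spec.normalize_mean, dtype=np.float32)[:, None, None]
    std = np.asarray(spec.normalize_std, dtype=np.float32)[:, None, None]
    return ((chw - mean) / std).astype(np.float32)
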