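"""Generator correctness: geometry, determinism, ground truth, separability."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from helpers import flood_fill_components
from longfission.datasetprep import resize_gray
from longfission.synthgen import (
    CellSpec,
    ClassGeometry,
    SynthConfig,
    cell_mask,
    generate_dataset,
    generate_microscope_image,
    render_cell,
)


def blank(shape=(96, 96), level=0.85):
    return np.full(shape, level, dtype=np.float32)


class TestRenderCell:
    def test_plain_rod_is_single_component(self):
        spec = CellSpec(center=(48, 48), length=30, width=10, orientation=0.7)
        img = render_cell(blank(), spec)
        mask = img < 0.5
        assert flood_fill_components(mask, 8).max() == 1

    def test_rendered_aspect_ratio_matches_spec(self):
        # width 20, length 30 -> major/minor extent ratio 1.5 up to raster error
        spec = CellSpec(center=(48, 48), length=30, width=20, orientation=0.0, septum="longitudinal")
        mask = cell_mask((96, 96), spec)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        major = cols[-1] - cols[0] + 1
        minor = rows[-1] - rows[0] + 1
        assert major / minor == pytest.approx(1.5, abs=0.15)

    def test_crease_keeps_mask_connected(self):
        spec = CellSpec(center=(48, 48), length=32, width=12, orientation=0.4, crease_width=2)
        mask = cell_mask((96, 96), spec)
        assert flood_fill_components(mask, 8).max() == 1

    def test_septum_is_darker_than_body(self):
        for kind in ("longitudinal", "transverse"):
            spec = CellSpec(center=(48, 48), length=30, width=14, orientation=0.0, septum=kind)
            img = render_cell(blank(), spec)
            body = cell_mask((96, 96), spec)
            assert img[body].min() < spec.intensity - 1e-6

    def test_out_of_canvas_rejected(self):
        spec = CellSpec(center=(5, 5), length=30, width=10, orientation=0.3)
        with pytest.raises(ValueError, match="does not fit"):
            render_cell(blank((48, 48)), spec)

    def test_invert_renders_bright_cell(self):
        spec = CellSpec(center=(48, 48), length=24, width=8, orientation=1.0)
        img = render_cell(blank(level=0.15), spec, invert=True)
        assert img.max() > 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(length=5, width=10),  # length < width
            dict(length=10, width=2),  # width < 3
            dict(length=10, width=5, orientation=3.5),  # orientation out of range
            dict(length=10, width=5, crease_width=5.0),  # crease >= width
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(center=(20, 20), orientation=0.0)
        with pytest.raises(ValueError):
            CellSpec(**{**base, **kwargs})


class TestGenerateImage:
    def test_cell_count_matches_request(self, rng):
        config = SynthConfig(images_per_class=1, cells_per_image=(5, 5))
        _, gt = generate_microscope_image(config, rng)
        assert len(gt.cells) == 5

    def test_same_seed_is_bit_identical(self):
        config = SynthConfig(images_per_class=1, seed=3)
        img1, gt1 = generate_microscope_image(config, np.random.default_rng(3), class_id=1)
        img2, gt2 = generate_microscope_image(config, np.random.default_rng(3), class_id=1)
        assert np.array_equal(img1, img2)
        assert gt1 == gt2

    def test_zero_noise_single_cell_equals_render(self):
        config = SynthConfig(images_per_class=1, cells_per_image=(1, 1), background_noise_sd=0.0)
        img, gt = generate_microscope_image(config, np.random.default_rng(5))
        redrawn = render_cell(np.full(config.canvas, config.background_level, dtype=np.float32), gt.cells[0].spec)
        assert np.array_equal(img, np.clip(redrawn, 0, 1))

    def test_boxes_lie_within_canvas(self, rng):
        config = SynthConfig(images_per_class=1, cells_per_image=(4, 6))
        for class_id in (0, 1):
            _, gt = generate_microscope_image(config, rng, class_id=class_id)
            for cell in gt.cells:
                assert 0 <= cell.box.row0 < cell.box.row1 <= config.canvas[0]
                assert 0 <= cell.box.col0 < cell.box.col1 <= config.canvas[1]

    def test_crowded_canvas_raises_with_context(self):
        config = SynthConfig(
            images_per_class=1, cells_per_image=(60, 60), canvas=(64, 64), max_retries=5,
            class_geometry={0: ClassGeometry(length_range=(20.0, 24.0), width_to_length=(0.55, 0.8),
                                             septum_probs={"longitudinal": 1.0, "transverse": 0.0, "none": 0.0})},
        )
        with pytest.raises(RuntimeError, match="retries"):
            generate_microscope_image(config, np.random.default_rng(0))


class TestGenerateDataset:
    def test_counts_labels_and_determinism(self, tmp_path):
        config = SynthConfig(images_per_class=4, cells_per_image=(1, 2), canvas=(128, 128), seed=9)
        manifest = generate_dataset(config, tmp_path / "a")
        assert len(manifest) == 8
        assert set(manifest["class_id"]) == {0, 1}
        for cls in ("longitudinal_division", "other_division"):
            assert len(list((tmp_path / "a" / cls).glob("*.png"))) == 4
        generate_dataset(config, tmp_path / "b")

        def digest(root: Path) -> list[tuple[str, str]]:
            return [
                (p.name, hashlib.sha256(p.read_bytes()).hexdigest())
                for p in sorted(root.rglob("*.png")) + sorted(root.rglob("*.csv"))
            ]

        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_zero_images_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            SynthConfig(images_per_class=0)


class TestSeparability:
    def test_small_classifier_separates_classes(self):
        """The two classes must be learnable: a logistic model on raw pixels of
        ground-truth crops reaches >= 95% held-out accuracy (3-seed average)."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        accs = []
        for seed in (0, 1, 2):
            config = SynthConfig(images_per_class=50, cells_per_image=(1, 2), canvas=(160, 160), seed=seed)
            rng = np.random.default_rng(seed)
            feats, labels = [], []
            for class_id in (0, 1):
                for _ in range(config.images_per_class):
                    img, gt = generate_microscope_image(config, rng, class_id=class_id)
                    for cell in gt.cells:
                        crop = img[cell.box.row0 : cell.box.row1, cell.box.col0 : cell.box.col1]
                        feats.append(resize_gray(crop, (24, 24)).ravel())
                        labels.append(class_id)
            x_tr, x_te, y_tr, y_te = train_test_split(
                np.asarray(feats), np.asarray(labels), test_size=0.33, random_state=seed, stratify=labels
            )
            clf = LogisticRegression(max_iter=3000).fit(x_tr, y_tr)
            accs.append(clf.score(x_te, y_te))
        assert float(np.mean(accs)) >= 0.95
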