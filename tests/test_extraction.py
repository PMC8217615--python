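"""Extraction: binarization, component labeling, boxes, crops, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import flood_fill_components, same_partition
from longfission.extraction import (
    BoundingBox,
    ExtractionConfig,
    binarize,
    bounding_boxes,
    extract_crops,
    extract_image,
    label_components,
    load_png,
    pad_box,
)
from longfission.synthgen import SynthConfig, cell_mask, generate_microscope_image


class TestBinarize:
    def test_all_dark_image_is_all_foreground(self):
        out = binarize(np.zeros((8, 8)), ExtractionConfig(threshold=0.5))
        assert out.all()

    def test_otsu_foreground_close_to_rendered_mask(self, rng):
        config = SynthConfig(images_per_class=1, cells_per_image=(1, 1))
        img, gt = generate_microscope_image(config, rng)
        mask = cell_mask(img.shape, gt.cells[0].spec)
        fg = binarize(img, ExtractionConfig(threshold="otsu"))
        assert fg.sum() == pytest.approx(mask.sum(), rel=0.10)

    def test_invert_complements_foreground(self, rng):
        img = rng.random((16, 16))
        img[img == 0.5] = 0.4  # avoid ties at the threshold
        a = binarize(img, ExtractionConfig(threshold=0.5, invert=False))
        b = binarize(img, ExtractionConfig(threshold=0.5, invert=True))
        assert not (a & b).any()
        assert (a | b).sum() == img.size - (img == 0.5).sum()

    def test_constant_image_under_otsu_raises(self):
        with pytest.raises(ValueError, match="fixed threshold"):
            binarize(np.full((8, 8), 0.3), ExtractionConfig(threshold="otsu"))


class TestLabelComponents:
    def test_diagonal_touch_depends_on_connectivity(self):
        img = np.zeros((4, 4), dtype=bool)
        img[1, 1] = img[2, 2] = True
        assert label_components(img, 8).count == 1
        assert label_components(img, 4).count == 2

    def test_empty_image_has_zero_components(self):
        assert label_components(np.zeros((5, 5), dtype=bool), 8).count == 0

    def test_ids_follow_raster_scan_order(self):
        img = np.zeros((6, 6), dtype=bool)
        img[4, 0] = True  # later in raster order
        img[0, 5] = True  # first foreground pixel in raster order
        lab = label_components(img, 8).labels
        assert lab[0, 5] == 1 and lab[4, 0] == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_flood_fill_oracle(self, seed):
        raster = np.random.default_rng(seed).random((32, 32)) < 0.4
        for conn in (4, 8):
            mine = label_components(raster, conn).labels
            oracle = flood_fill_components(raster, conn)
            assert same_partition(mine, oracle)
            assert mine.max() == oracle.max()

    def test_area_conservation(self, rng):
        raster = rng.random((40, 40)) < 0.3
        lab = label_components(raster, 8)
        areas = [a for _, a in bounding_boxes(lab, min_area=0)]
        assert sum(areas) == int(raster.sum())


class TestBoundingBoxes:
    def test_single_block_box_is_tight(self):
        img = np.zeros((10, 10), dtype=bool)
        img[2:5, 5:8] = True
        boxes = bounding_boxes(label_components(img, 8), min_area=0)
        assert boxes == [(BoundingBox(2, 5, 5, 8), 9)]

    def test_min_area_filters_small_components(self):
        img = np.zeros((30, 30), dtype=bool)
        img[0:2, 0:2] = True  # area 4
        img[10:20, 10:22] = True  # area 120
        boxes = bounding_boxes(label_components(img, 8), min_area=50)
        assert len(boxes) == 1 and boxes[0][1] == 120

    def test_min_area_zero_keeps_every_component(self, rng):
        raster = rng.random((32, 32)) < 0.2
        lab = label_components(raster, 8)
        assert len(bounding_boxes(lab, min_area=0)) == lab.count

    def test_flip_symmetry(self, rng):
        raster = rng.random((24, 24)) < 0.3
        boxes = {(b.row0, b.col0, b.row1, b.col1) for b, _ in bounding_boxes(label_components(raster, 8), 0)}
        flipped = bounding_boxes(label_components(raster[::-1], 8), 0)
        n = raster.shape[0]
        back = {(n - b.row1, b.col0, n - b.row0, b.col1) for b, _ in flipped}
        assert boxes == back


class TestExtractCrops:
    def test_crop_equals_source_region(self, tmp_path, rng):
        img = rng.random((12, 12)).astype(np.float32)
        [path] = extract_crops(img, [BoundingBox(2, 5, 5, 8)], tmp_path, padding=0)
        crop = load_png(path)
        expected = np.clip(np.rint(img[2:5, 5:8] * 255), 0, 255) / 255
        assert np.allclose(crop, expected, atol=1e-6)
        assert crop.shape == (3, 3)

    def test_corner_padding_clips_to_bounds(self, tmp_path, rng):
        img = rng.random((10, 10)).astype(np.float32)
        [path] = extract_crops(img, [BoundingBox(0, 0, 3, 3)], tmp_path, padding=2)
        assert load_png(path).shape == (5, 5)  # clipped at the corner

    def test_five_cell_image_gives_five_crops(self, tmp_path):
        config = SynthConfig(images_per_class=1, cells_per_image=(5, 5))
        img, gt = generate_microscope_image(config, np.random.default_rng(2))
        boxes = extract_image(img, ExtractionConfig(min_area=30))
        paths = extract_crops(img, [b for b, _ in boxes], tmp_path)
        assert len(paths) == len(gt.cells) == 5


class TestPipelineRecovery:
    def test_every_planted_cell_recovered_with_iou(self, tiny_synth_config):
        """binarize -> label -> boxes recovers each ground-truth cell (IoU >= 0.8)."""
        rng = np.random.default_rng(tiny_synth_config.seed)
        for class_id in (0, 1):
            for _ in range(tiny_synth_config.images_per_class):
                img, gt = generate_microscope_image(tiny_synth_config, rng, class_id=class_id)
                boxes = extract_image(img, ExtractionConfig(min_area=30))
                assert len(boxes) == len(gt.cells)
                for cell in gt.cells:
                    assert max(b.iou(cell.box) for b, _ in boxes) >= 0.8


def test_pad_box_clips_to_shape():
    assert pad_box(BoundingBox(0, 3, 4, 6), 2, (10, 7)) == BoundingBox(0, 1, 6, 7)
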