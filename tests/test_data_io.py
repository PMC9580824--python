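"""Image/mask/annotation I/O, polygon rasterisation, cropping and splitting."""

import json

import numpy as np
import pytest
import tifffile
from PIL import Image

from folliseg import data_io, metrics
from folliseg.data_io import (AnnotationError, PolygonAnnotation, crop_window,
                              load_image, load_labelme, load_mask, make_manifest,
                              polygons_to_mask, save_image, save_mask,
                              split_dataset)


def point_in_polygon_loop(x, y, pts):
    """Even-odd crossing-number oracle for a single point."""
    inside = False
    n = len(pts)
    for k in range(n):
        x1, y1 = pts[k]
        x2, y2 = pts[(k + 1) % n]
        if (y1 <= y) != (y2 <= y):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_at:
                inside = not inside
    return inside


class TestImageIO:
    def test_eight_bit_scale_anchor(self, tmp_path):
        arr = np.array([[0, 128, 255]], dtype=np.uint8)
        Image.fromarray(arr, mode="L").save(tmp_path / "a.png")
        img = load_image(tmp_path / "a.png")
        assert img[0, 2] == 1.0 and img[0, 0] == 0.0
        assert img[0, 1] == pytest.approx(128 / 255)

    def test_sixteen_bit_tiff_scale_anchor(self, tmp_path):
        arr = np.array([[0, 65535]], dtype=np.uint16)
        tifffile.imwrite(tmp_path / "a.tiff", arr)
        img = load_image(tmp_path / "a.tiff")
        assert img[0, 1] == 1.0 and img[0, 0] == 0.0

    def test_round_trip_within_quantisation_bound(self, tmp_path, rng):
        img = rng.uniform(0, 1, (16, 16))
        save_image(img, tmp_path / "r.png")
        back = load_image(tmp_path / "r.png")
        assert np.max(np.abs(back - img)) <= 1 / (2 * 255) + 1e-12

    def test_rgb_collapsed_by_luminance(self, tmp_path):
        arr = np.zeros((2, 2, 3), dtype=np.uint8)
        arr[..., 1] = 255  # pure green
        Image.fromarray(arr, mode="RGB").save(tmp_path / "rgb.png")
        img = load_image(tmp_path / "rgb.png")
        assert img[0, 0] == pytest.approx(0.587, abs=1e-3)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            load_image(tmp_path / "nope.png")


class TestMaskIO:
    def test_round_trip(self, tmp_path, rng):
        mask = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
        save_mask(mask, tmp_path / "m.png")
        np.testing.assert_array_equal(load_mask(tmp_path / "m.png"), mask)

    def test_intermediate_gray_values_rejected_not_thresholded(self, tmp_path):
        arr = np.array([[0, 128, 255]], dtype=np.uint8)
        Image.fromarray(arr, mode="L").save(tmp_path / "bad.png")
        with pytest.raises(AnnotationError, match="0/255"):
            load_mask(tmp_path / "bad.png")


class TestPolygons:
    def test_axis_aligned_square(self):
        ann = PolygonAnnotation("follicle", ((0, 0), (4, 0), (4, 4), (0, 4)))
        mask = polygons_to_mask([ann], 8, 8)
        expected = np.zeros((8, 8), np.uint8)
        expected[:4, :4] = 1
        np.testing.assert_array_equal(mask, expected)

    def test_empty_annotation_list(self):
        assert polygons_to_mask([], 5, 5).sum() == 0

    def test_disjoint_triangles_additive(self):
        t1 = PolygonAnnotation("a", ((0, 0), (6, 0), (0, 6)))
        t2 = PolygonAnnotation("b", ((10, 10), (15, 10), (10, 15)))
        m1 = polygons_to_mask([t1], 16, 16)
        m2 = polygons_to_mask([t2], 16, 16)
        both = polygons_to_mask([t1, t2], 16, 16)
        assert both.sum() == m1.sum() + m2.sum()
        np.testing.assert_array_equal(both, m1 | m2)

    def test_matches_point_in_polygon_loop_oracle(self, rng):
        pts = [(float(x), float(y)) for x, y in rng.uniform(1, 11, (5, 2))]
        ann = PolygonAnnotation("p", tuple(pts))
        mask = polygons_to_mask([ann], 12, 12)
        for i in range(12):
            for j in range(12):
                assert bool(mask[i, j]) == point_in_polygon_loop(j + 0.5, i + 0.5, pts)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(AnnotationError, match="3 vertices"):
            PolygonAnnotation("bad", ((0, 0), (1, 1)))

    def test_labelme_json_round_trip(self, tmp_path):
        doc = {"shapes": [{"label": "follicle",
                           "points": [[1, 1], [5, 1], [5, 5], [1, 5]]}]}
        path = tmp_path / "ann.json"
        path.write_text(json.dumps(doc))
        anns = load_labelme(path)
        assert len(anns) == 1 and anns[0].label == "follicle"
        assert polygons_to_mask(anns, 8, 8).sum() == 16

    def test_labelme_without_shapes_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{}")
        with pytest.raises(AnnotationError, match="shapes"):
            load_labelme(path)


class TestCropWindow:
    def test_full_window_is_identity(self, rng):
        img = rng.uniform(size=(6, 9))
        np.testing.assert_array_equal(crop_window(img, (0, 0), (6, 9)), img)

    def test_literal_sub_block(self):
        img = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(crop_window(img, (1, 2), (2, 2)),
                                      img[1:3, 2:4])

    def test_crop_commutes_with_scores(self, rng):
        sr = (rng.uniform(size=(20, 30)) > 0.5).astype(np.uint8)
        gt = (rng.uniform(size=(20, 30)) > 0.5).astype(np.uint8)
        win, size = (4, 6), (10, 12)
        direct = metrics.scores(crop_window(sr, win, size), crop_window(gt, win, size))
        oracle = metrics.scores(sr[4:14, 6:18], gt[4:14, 6:18])
        assert direct == oracle

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            crop_window(np.zeros((8, 8)), (4, 4), (8, 8))


class TestSplit:
    def test_documented_rounding_rule(self):
        labels = split_dataset(10, (0.7, 0.15, 0.15), seed=1)
        counts = {s: labels.count(s) for s in ("train", "val", "test")}
        assert counts == {"train": 7, "val": 1, "test": 2}

    def test_deterministic(self):
        assert split_dataset(20, seed=5) == split_dataset(20, seed=5)
        assert split_dataset(20, seed=5) != split_dataset(20, seed=6)

    def test_partition_property(self):
        labels = split_dataset(23, (0.6, 0.2, 0.2), seed=0)
        assert len(labels) == 23 and all(s in ("train", "val", "test") for s in labels)

    @pytest.mark.parametrize("ratios", [(0.5, 0.5, 0.5), (0.7, 0.2, 0.2), (-0.1, 0.6, 0.5)])
    def test_invalid_ratios_rejected(self, ratios):
        with pytest.raises(ValueError, match="ratios"):
            split_dataset(10, ratios, seed=0)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_dataset(2, seed=0)

    def test_manifest_pairs_preserved(self):
        pairs = [(f"i{k}.png", f"m{k}.png") for k in range(10)]
        manifest = make_manifest(pairs, seed=2)
        assert {(i, m) for i, m, _ in manifest.entries} == set(pairs)
        assert len(manifest.paths("train")) == 7
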