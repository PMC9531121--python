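"""Annotation I/O, rasterization, preprocessing, and splitting."""

import json
import warnings

import numpy as np
import pytest

from tongue_mtl import data as D
from tongue_mtl import synthetic as syn


# -- independent point-in-polygon oracle (crossing number, even-odd) -------

def _inside(px, py, verts):
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def _brute_mask(verts, H, W):
    m = np.zeros((H, W), np.uint8)
    for y in range(H):
        for x in range(W):
            m[y, x] = _inside(x + 0.5, y + 0.5, verts)
    return m


class TestReadLabelme:
    SQUARE = {"shapes": [{"label": "tongue", "shape_type": "polygon",
                          "points": [[1, 1], [5, 1], [5, 4], [1, 4]]}]}

    def test_single_polygon_passthrough(self):
        polys = D.read_labelme(json.dumps(self.SQUARE))
        assert len(polys) == 1
        np.testing.assert_array_equal(polys[0].vertices,
                                      [[1, 1], [5, 1], [5, 4], [1, 4]])

    def test_zero_shapes_is_empty_list(self):
        assert D.read_labelme({"shapes": []}) == []

    def test_missing_shapes_key_raises(self):
        with pytest.raises(D.LabelmeFormatError, match="shapes"):
            D.read_labelme({"version": "5.0.0"})

    def test_non_polygon_shape_named_in_error(self):
        doc = {"shapes": [{"label": "dot", "shape_type": "point",
                           "points": [[1, 1]]}]}
        with pytest.raises(D.LabelmeFormatError, match="dot"):
            D.read_labelme(doc)

    def test_emitted_annotation_roundtrip_jaccard(self):
        """Generator-emitted polygons re-rasterize to (almost) the same
        mask; 20 scenes, Jaccard >= 0.98."""
        for s in range(20):
            mask = syn.generate_scene(s, (64, 64)).mask
            doc = syn.mask_to_labelme(mask)
            polys = D.read_labelme(doc)
            back = D.polygons_to_mask(polys, mask.shape)
            inter = np.logical_and(mask, back).sum()
            union = np.logical_or(mask, back).sum()
            assert inter / union >= 0.98


class TestPolygonsToMask:
    def test_axis_aligned_rectangle_pixel_count(self):
        poly = D.Polygon([[0, 0], [4, 0], [4, 3], [0, 3]])
        mask = D.polygons_to_mask([poly], (10, 10))
        assert mask.sum() == 12
        assert mask[:3, :4].all()

    def test_full_frame_polygon_is_all_ones(self):
        poly = D.Polygon([[0, 0], [8, 0], [8, 8], [0, 8]])
        assert D.polygons_to_mask([poly], (8, 8)).all()

    def test_two_disjoint_triangles_areas_add(self):
        t1 = D.Polygon([[0, 0], [6, 0], [0, 6]])
        t2 = D.Polygon([[20, 20], [28, 20], [20, 28]])
        m1 = D.polygons_to_mask([t1], (32, 32))
        m2 = D.polygons_to_mask([t2], (32, 32))
        both = D.polygons_to_mask([t1, t2], (32, 32))
        assert both.sum() == m1.sum() + m2.sum()

    def test_degenerate_polygon_raises(self):
        line = D.Polygon([[1, 1], [5, 1], [9, 1]])
        with pytest.raises(ValueError, match="empty"):
            D.polygons_to_mask([line], (12, 12))

    def test_matches_crossing_number_oracle_on_random_polygons(self):
        """Pixel-exact agreement with a brute-force even-odd oracle on 200
        random triangles and convex quadrilaterals in a 32x32 frame."""
        rng = np.random.default_rng(7)
        for trial in range(200):
            k = 3 if trial % 2 == 0 else 4
            pts = rng.uniform(1, 31, (k, 2))
            if k == 4:      # order by angle around the centroid -> simple
                c = pts.mean(axis=0)
                pts = pts[np.argsort(np.arctan2(*(pts - c).T[::-1]))]
            try:
                mask = D.polygons_to_mask([D.Polygon(pts)], (32, 32))
            except ValueError:
                continue    # sliver missing every pixel center: oracle-free
            np.testing.assert_array_equal(mask, _brute_mask(pts, 32, 32))


class TestExtractTongue:
    def test_all_ones_mask_is_identity(self):
        img = np.random.default_rng(0).random((8, 8, 3))
        np.testing.assert_array_equal(
            D.extract_tongue(img, np.ones((8, 8), np.uint8)), img)

    def test_single_pixel_mask(self):
        img = np.random.default_rng(1).random((8, 8, 3))
        mask = np.zeros((8, 8), np.uint8)
        mask[3, 4] = 1
        out = D.extract_tongue(img, mask)
        assert (out != 0).sum() == 3
        np.testing.assert_array_equal(out[3, 4], img[3, 4])

    def test_elementwise_product_oracle_and_idempotence(self):
        rng = np.random.default_rng(2)
        img = rng.random((16, 16, 3))
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        out = D.extract_tongue(img, mask)
        np.testing.assert_array_equal(out, img * mask[:, :, None])
        np.testing.assert_array_equal(D.extract_tongue(out, mask), out)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            D.extract_tongue(np.zeros((4, 4, 3)), np.zeros((5, 5)))


class TestResizeNormalize:
    def test_matching_size_without_normalization_is_identity(self):
        img = np.random.default_rng(3).random((224, 224, 3)).astype(np.float32)
        mask = np.ones((224, 224), np.uint8)
        out = D.resize_normalize(img, mask, side=224, normalize="unit")
        np.testing.assert_array_equal(out.image, img.transpose(2, 0, 1))

    def test_constant_image_stays_constant_after_resize(self):
        img = np.full((40, 60, 3), 0.25, np.float32)
        out = D.resize_normalize(img, np.ones((40, 60)), side=64,
                                 normalize="unit")
        np.testing.assert_allclose(out.image, 0.25, atol=1e-6)

    def test_imagenet_normalization_values(self):
        img = np.full((32, 32, 3), 0.5, np.float32)
        out = D.resize_normalize(img, np.ones((32, 32)), side=32)
        expect = (0.5 - D.IMAGENET_MEAN) / D.IMAGENET_STD
        np.testing.assert_allclose(out.image[:, 0, 0], expect, rtol=1e-5)

    def test_mask_stays_binary_under_upscaling(self):
        mask = np.indices((8, 8)).sum(axis=0) % 2
        out = D.resize_normalize(np.random.default_rng(4).random((8, 8, 3)),
                                 mask, side=224, normalize="unit")
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_nonfinite_pixels_rejected(self):
        img = np.full((16, 16, 3), np.nan, np.float32)
        with pytest.raises(ValueError, match="finite"):
            D.resize_normalize(img, np.ones((16, 16)), side=32)


class TestAugmentPair:
    def test_zero_ranges_give_identity(self):
        rng = np.random.default_rng(5)
        img = rng.random((32, 32, 3)).astype(np.float32)
        mask = (rng.random((32, 32)) > 0.6).astype(np.uint8)
        out_i, out_m = D.augment_pair(img, mask, seed=0, max_translate=0.0,
                                      max_rotate_deg=0.0)
        np.testing.assert_allclose(out_i, img, atol=1e-6)
        np.testing.assert_array_equal(out_m, mask)

    def test_same_seed_same_output(self):
        img = syn.generate_scene(0, (64, 64))
        a = D.augment_pair(img.pixels, img.mask, seed=11)
        b = D.augment_pair(img.pixels, img.mask, seed=11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_mask_transforms_consistently_with_image(self):
        """Warping the mask (nearest) vs. warping it as an intensity image
        (bilinear + threshold) agree with Jaccard >= 0.95 on 20 scenes."""
        for s in range(20):
            img = syn.generate_scene(s, (64, 64))
            _, warped = D.augment_pair(img.pixels, img.mask, seed=100 + s)
            soft, _ = D.augment_pair(
                np.repeat(img.mask[:, :, None], 3, 2).astype(np.float32),
                img.mask, seed=100 + s)
            alt = (soft[:, :, 0] > 0.5).astype(np.uint8)
            union = np.logical_or(warped, alt).sum()
            if union == 0:
                continue
            assert np.logical_and(warped, alt).sum() / union >= 0.95


class TestSplitDataset:
    @staticmethod
    def _ids(n, label):
        return [(f"{label}{i}", label) for i in range(n)]

    def test_clinical_scale_split_sizes(self):
        pairs = self._ids(546, "high") + self._ids(468, "low")
        split = D.split_dataset(pairs, seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (709, 151, 154)
        # floor rule per class: floor(.7*546)=382, floor(.15*546)=81, rest 83
        high_train = sum(1 for i in split.train if i.startswith("high"))
        assert high_train == 382
        assert sum(1 for i in split.val if i.startswith("high")) == 81
        assert sum(1 for i in split.test if i.startswith("low")) == 71

    def test_single_class_ten_items(self):
        split = D.split_dataset(self._ids(10, "x"), seed=1)
        assert (len(split.train), len(split.val), len(split.test)) == (7, 1, 2)

    def test_same_seed_reproduces_split(self):
        pairs = self._ids(20, "a") + self._ids(15, "b")
        s1 = D.split_dataset(pairs, seed=3)
        s2 = D.split_dataset(pairs, seed=3)
        assert s1 == s2

    def test_partition_is_disjoint_and_exhaustive(self):
        pairs = self._ids(37, "a") + self._ids(23, "b")
        split = D.split_dataset(pairs, seed=5)
        all_ids = split.train + split.val + split.test
        assert len(all_ids) == len(set(all_ids)) == 60

    def test_stratified_fractions_within_one_item(self):
        for n_a, n_b in ((40, 30), (11, 9), (100, 3)):
            pairs = self._ids(n_a, "a") + self._ids(n_b, "b")
            split = D.split_dataset(pairs, seed=7)
            for lab, n in (("a", n_a), ("b", n_b)):
                got = sum(1 for i in split.train if i.startswith(lab))
                assert abs(got - 0.70 * n) <= 1.0

    def test_tiny_class_lumped_into_train_with_warning(self):
        pairs = self._ids(10, "big") + self._ids(2, "rare")
        with pytest.warns(UserWarning, match="rare"):
            split = D.split_dataset(pairs, seed=0)
        assert all(f"rare{i}" in split.train for i in range(2))

    def test_json_roundtrip(self):
        split = D.split_dataset(self._ids(9, "z"), seed=2)
        assert D.SplitIndex.from_json(split.to_json()) == split
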