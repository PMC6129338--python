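"""Preprocessing chain: filtering, rotation geometry, distance transform,
medial axis and the ten-segment vertical partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from dermatex import preprocess as pp
from dermatex import synth


def brute_force_median(img, window):
    """Per-pixel sort-and-pick-middle with edge replication."""
    r = window // 2
    padded = np.pad(img, r, mode="edge")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            block = padded[i:i + window, j:j + window].ravel()
            out[i, j] = np.sort(block)[block.size // 2]
    return out


def brute_force_edt(mask):
    """Exhaustive nearest-background search."""
    out = np.zeros(mask.shape, dtype=float)
    bg = np.argwhere(~mask)
    for (i, j) in np.argwhere(mask):
        d2 = ((bg - (i, j)) ** 2).sum(axis=1)
        out[i, j] = np.sqrt(d2.min())
    return out


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 40, dtype=np.uint8)
        np.testing.assert_array_equal(pp.median_filter(img), img)

    def test_single_outlier_removed(self):
        img = np.full((5, 5), 10, dtype=np.uint8)
        img[2, 2] = 255
        assert pp.median_filter(img)[2, 2] == 10

    @pytest.mark.parametrize("window", [2, 0, -3])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError, match="window"):
            pp.median_filter(np.zeros((8, 8), dtype=np.uint8), window)

    @given(hnp.arrays(np.uint8, (16, 16)))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle(self, img):
        got = pp.median_filter(img, 3)
        np.testing.assert_array_equal(got, brute_force_median(img, 3))

    @given(hnp.arrays(np.uint8, (12, 12)))
    @settings(max_examples=25, deadline=None)
    def test_output_range_within_input_range(self, img):
        out = pp.median_filter(img, 3)
        assert out.min() >= img.min() and out.max() <= img.max()


class TestRotationGeometry:
    @pytest.mark.parametrize("w, h, theta, expected", [
        (100, 50, 0.0, (100, 50)),
        (100, 50, 90.0, (50, 100)),
        (100, 50, 30.0, (112, 94)),
    ])
    def test_canvas_size(self, w, h, theta, expected):
        assert pp.rotated_canvas_size(w, h, theta) == expected

    def test_zero_rotation_is_identity(self, rng):
        img = rng.integers(0, 256, (20, 30)).astype(np.uint8)
        out, params = pp.rotate_image(img, 0.0)
        np.testing.assert_array_equal(out, img)

    def test_right_angle_rotation_is_bijective(self, rng):
        img = rng.integers(0, 256, (20, 30)).astype(np.uint8)
        out90, _ = pp.rotate_image(img, 90.0)
        back, _ = pp.rotate_image(out90, -90.0)
        np.testing.assert_array_equal(back, img)
        assert sorted(out90.ravel()) == sorted(img.ravel())

    def test_180_degrees_reflects_through_center(self):
        img = np.zeros((11, 15), dtype=np.uint8)
        img[2, 3] = 200
        out, _ = pp.rotate_image(img, 180.0)
        assert out[11 - 1 - 2, 15 - 1 - 3] == 200


class TestOrientation:
    @staticmethod
    def ellipse(theta_deg):
        return synth._superellipse_mask((128, 128), theta_deg, 50.0, 20.0,
                                        exponent=2.0)

    def test_horizontal_ellipse(self):
        assert abs(pp.estimate_orientation(self.ellipse(0.0))) < 1.0

    @pytest.mark.parametrize("theta", [30.0, -40.0, 15.0])
    def test_rotated_ellipse_angle_recovered(self, theta):
        assert abs(pp.estimate_orientation(self.ellipse(theta)) - theta) < 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pp.estimate_orientation(np.zeros((8, 8), dtype=bool))

    def test_rotating_by_negated_angle_horizontalizes(self):
        mask = self.ellipse(25.0).astype(np.uint8) * 255
        theta = pp.estimate_orientation(mask > 0)
        rot, _ = pp.rotate_image(mask, -theta)
        assert abs(pp.estimate_orientation(rot > 0)) < 2.0


class TestBinarize:
    def test_bimodal_exact_separation(self):
        img = np.full((20, 20), 20, dtype=np.uint8)
        img[5:15, 5:15] = 200
        mask = pp.binarize(img)
        np.testing.assert_array_equal(mask, img == 200)

    def test_constant_image_warns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = pp.binarize(np.zeros((16, 16), dtype=np.uint8))
        assert not mask.any()

    def test_recovers_synthetic_epithelium(self, normal_image):
        img, _ = normal_image
        fg_truth = synth._superellipse_mask((256, 256), 10.0,
                                            0.44 * 256, 0.23 * 256)
        mask = pp.binarize(pp.to_gray(pp.median_filter(img)))
        assert (mask & fg_truth).sum() / fg_truth.sum() > 0.95


class TestDistanceTransform:
    def test_three_four_five_triangle(self):
        mask = np.ones((12, 12), dtype=bool)
        mask[0, 0] = False
        assert pp.euclidean_distance_transform(mask)[3, 4] == pytest.approx(5.0)

    def test_horizontal_strip_center_distance(self):
        mask = np.zeros((20, 15), dtype=bool)
        mask[5:12] = True  # height-7 strip
        dist = pp.euclidean_distance_transform(mask)
        assert dist[8].max() == pytest.approx(4.0)

    def test_all_foreground_rejected(self):
        with pytest.raises(ValueError, match="background"):
            pp.euclidean_distance_transform(np.ones((8, 8), dtype=bool))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(5):
            mask = rng.random((32, 32)) < 0.6
            mask[0, 0] = False
            got = pp.euclidean_distance_transform(mask)
            np.testing.assert_allclose(got, brute_force_edt(mask), atol=0)


class TestMedialAxis:
    def test_symmetric_strip_axis_at_midline(self):
        mask = np.zeros((30, 40), dtype=bool)
        mask[10:21] = True  # rows 10..20 inclusive
        dist = pp.euclidean_distance_transform(mask)
        axis = pp.extract_medial_axis(dist, mask)
        assert (axis.points[:, 0] == 15).all()
        top, left, bottom, right = axis.bounding_box
        assert axis.points.shape[0] == right - left + 1

    def test_narrow_foreground_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 4:9] = True  # 5 columns < 10
        dist = pp.euclidean_distance_transform(mask)
        with pytest.raises(ValueError, match="columns"):
            pp.extract_medial_axis(dist, mask)

    def test_axis_near_ellipse_midline(self):
        mask = synth._superellipse_mask((120, 200), 0.0, 90.0, 35.0,
                                        exponent=2.0)
        dist = pp.euclidean_distance_transform(mask)
        axis = pp.extract_medial_axis(dist, mask)
        rows = axis.points[:, 0]
        n = rows.size
        central = rows[n // 10: -n // 10]  # central 80% of columns
        midline = (120 - 1) / 2
        assert np.abs(central - midline).max() <= 2


class TestTenSegments:
    @staticmethod
    def strip_fixture(ncols):
        # full-width strip: the ridge is exactly the horizontal midline
        mask = np.zeros((30, ncols), dtype=bool)
        mask[10:21, :] = True
        dist = pp.euclidean_distance_transform(mask)
        axis = pp.extract_medial_axis(dist, mask)
        return pp.split_ten_segments(axis, mask), mask

    def test_straight_axis_equal_columns(self):
        segs, _ = self.strip_fixture(100)
        widths = [len(np.unique(np.nonzero(r)[1])) for r in segs.regions]
        assert widths == [10] * 10

    def test_remainder_spread_at_most_one_column(self):
        segs, _ = self.strip_fixture(105)
        widths = [len(np.unique(np.nonzero(r)[1])) for r in segs.regions]
        assert max(widths) - min(widths) <= 1

    def test_partition_contract(self, psoriasis_image):
        img, _ = psoriasis_image
        res = pp.preprocess_image(img)
        segs = res.segments.regions
        assert len(segs) == 10
        assert all(r.any() for r in segs)
        total = sum(int(r.sum()) for r in segs)
        union = np.zeros_like(segs[0])
        for r in segs:
            union |= r
        assert total == int(union.sum())  # pairwise disjoint
        top, left, bottom, right = res.axis.bounding_box
        box = np.zeros_like(res.mask)
        box[top:bottom + 1, left:right + 1] = True
        np.testing.assert_array_equal(union, res.mask & box)

    def test_deterministic_end_to_end(self, psoriasis_image):
        img, _ = psoriasis_image
        a = pp.preprocess_image(img)
        b = pp.preprocess_image(img)
        for ra, rb in zip(a.segments.regions, b.segments.regions):
            np.testing.assert_array_equal(ra, rb)
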