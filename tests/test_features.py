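import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from dermasp import compute_sp_features, extract_all, region_moments
from dermasp.islic import SuperpixelSet

from helpers import brute_force_convex_area, brute_force_moments, random_blob


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


class TestRegionMoments:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        area, _, cov = region_moments(mask)
        assert area == 1
        assert np.allclose(cov, [[1 / 12, 0], [0, 1 / 12]])

    def test_horizontal_bar_hand_sum(self):
        mask = np.zeros((3, 7), bool)
        mask[1, 1:6] = True  # 1x5 bar
        _, _, cov = region_moments(mask)
        assert cov[0, 1] == 0
        assert np.isclose(cov[0, 0], 2 + 1 / 12)  # var of {-2..2} + correction
        assert np.isclose(cov[1, 1], 1 / 12)

    def test_mirror_negates_cross_moment(self, rng):
        for _ in range(10):
            mask = random_blob(rng, 32)
            _, _, cov = region_moments(mask)
            _, _, cov_m = region_moments(mask[:, ::-1])
            assert np.allclose(np.diag(cov), np.diag(cov_m))
            assert np.isclose(cov[0, 1], -cov_m[0, 1])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_moments(np.zeros((4, 4), bool))


class TestComputeSpFeatures:
    def test_filled_square(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        fv = compute_sp_features(mask)
        assert fv.area == 100
        assert fv.convex_area == 100
        assert fv.eccentricity == 0
        assert fv.perimeter == 36  # closed chain over 36 border pixels

    def test_single_pixel_closed_form(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        fv = compute_sp_features(mask)
        assert fv.area == 1 and fv.eccentricity == 0
        assert np.isclose(fv.major_axis_length, 4 / np.sqrt(12))

    def test_digitized_ellipse_recovery(self):
        """Continuous ellipse (semi-axes 20/10) as closed-form oracle."""
        mask = np.zeros((64, 64), bool)
        rr, cc = draw_ellipse(32, 32, 10, 20)  # r-semi 10, c-semi 20
        mask[rr, cc] = True
        fv = compute_sp_features(mask)
        assert _angle_diff(fv.orientation, 0.0) < 2
        assert abs(fv.eccentricity - np.sqrt(1 - 0.25)) < 0.02

    def test_rotation_by_90_degrees_is_an_isometry(self, rng):
        for _ in range(10):
            mask = random_blob(rng, 40)
            a = compute_sp_features(mask)
            b = compute_sp_features(np.rot90(mask))
            assert a.area == b.area
            assert a.convex_area == b.convex_area
            assert np.isclose(a.eccentricity, b.eccentricity)
            assert np.isclose(a.major_axis_length, b.major_axis_length)
            if a.eccentricity > 1e-6:
                assert _angle_diff(a.orientation + 90, b.orientation) < 1e-6

    def test_oracle_equivalence_on_random_blobs(self, rng):
        """Moments/eigen path must agree with the explicit-loop oracle."""
        for _ in range(25):
            mask = random_blob(rng, 48)
            fv = compute_sp_features(mask)
            n, orient, ecc, major = brute_force_moments(mask)
            assert fv.area == n
            assert abs(fv.eccentricity - ecc) < 1e-6
            assert abs(fv.major_axis_length - major) < 1e-6
            if ecc > 1e-6:
                assert _angle_diff(fv.orientation, orient) < 1e-6
            assert fv.convex_area == brute_force_convex_area(mask)

    def test_convexity_equality_iff_convex(self):
        rect = np.zeros((12, 12), bool)
        rect[2:9, 3:10] = True
        fv = compute_sp_features(rect)
        assert fv.convex_area == fv.area
        ell = rect.copy()
        ell[2:6, 3:6] = False  # carve an L
        fv = compute_sp_features(ell)
        assert fv.convex_area > fv.area


class TestExtractAll:
    def _sp_set(self, labels, kept):
        counts = {int(l): int((labels == l).sum()) for l in np.unique(labels)}
        return SuperpixelSet(labels, tuple(kept), len(counts), counts)

    def test_one_record_per_kept_label(self):
        labels = np.ones((10, 10), dtype=int)
        labels[:, 5:] = 2
        recs = extract_all(self._sp_set(labels, (1, 2)), "img0", "nevus")
        assert len(recs) == 2
        assert {r["sp_label"] for r in recs} == {1, 2}
        assert all(r["image_id"] == "img0" and r["class"] == "nevus" for r in recs)

    def test_empty_kept_set(self):
        labels = np.ones((4, 4), dtype=int)
        assert extract_all(self._sp_set(labels, ()), "x", "melanoma") == []

    def test_end_to_end_records_satisfy_invariants(self, masked_nevus):
        from dermasp import SlicParams, filter_background_superpixels, slic_superpixels

        masked, mask = masked_nevus
        labels = slic_superpixels(masked, SlicParams())
        sp = filter_background_superpixels(labels, mask, 0.5, 100)
        recs = extract_all(sp, "img", "nevus")
        assert len(recs) == sp.n_kept > 0
        for r in recs:
            assert r["area"] >= 1
            assert r["convex_area"] >= r["area"]
            assert 0 <= r["eccentricity"] < 1
            assert -90 < r["orientation"] <= 90
            assert r["major_axis_length"] > 0
            assert np.isfinite(r["perimeter"])
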