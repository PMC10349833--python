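import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermasp import (
    SlicParams,
    enforce_connectivity,
    filter_background_superpixels,
    slic_superpixels,
)
from dermasp.islic import _components

from helpers import boundary_recall, two_tone_image


class TestSlic:
    def test_constant_image_regular_tiling(self):
        img = np.full((120, 120, 3), 128, np.uint8)
        labels = slic_superpixels(img, SlicParams(n_superpixels=9))
        areas = np.bincount(labels.ravel())[1:]
        assert labels.max() == 9
        assert (np.abs(areas - 1600) <= 0.25 * 1600).all()

    def test_two_tone_boundary_recall(self):
        img, edge = two_tone_image()
        labels = slic_superpixels(img, SlicParams(n_superpixels=2))
        assert boundary_recall(labels, edge) >= 0.9

    def test_deterministic(self, masked_nevus):
        masked, _ = masked_nevus
        a = slic_superpixels(masked, SlicParams())
        b = slic_superpixels(masked, SlicParams())
        assert np.array_equal(a, b)

    def test_partition_and_connectivity(self, masked_nevus):
        masked, _ = masked_nevus
        labels = slic_superpixels(masked, SlicParams())
        assert labels.min() == 1  # complete partition, compact labels
        assert set(np.unique(labels)) == set(range(1, labels.max() + 1))
        _, ncomp = _components(labels)
        assert ncomp == labels.max()
        assert 50 <= labels.max() <= 200

    def test_area_cv_on_constant_image(self):
        img = np.full((200, 200, 3), 90, np.uint8)
        labels = slic_superpixels(img, SlicParams(n_superpixels=100))
        areas = np.bincount(labels.ravel())[1:]
        assert areas.std() / areas.mean() <= 0.3

    def test_oversized_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            slic_superpixels(np.zeros((4, 4, 3), np.uint8), SlicParams(n_superpixels=17))

    def test_agrees_with_reference_slic_on_two_tone(self):
        """Independent cross-check against the scikit-image implementation."""
        from skimage.segmentation import slic as sk_slic

        img, edge = two_tone_image()
        ref = sk_slic(img, n_segments=2, compactness=10, start_label=1)
        assert boundary_recall(ref, edge) >= 0.9  # same contract as ours


class TestEnforceConnectivity:
    def test_connected_map_unchanged_up_to_relabel(self):
        labels = np.repeat(np.arange(1, 5), 8).reshape(4, 8).T.copy()
        out = enforce_connectivity(labels, min_size=2)
        # same partition: bijection between old and new labels
        pairs = {(int(a), int(b)) for a, b in zip(labels.ravel(), out.ravel())}
        assert len(pairs) == len(set(p[0] for p in pairs)) == len(set(p[1] for p in pairs))

    def test_small_orphan_absorbed(self):
        labels = np.ones((6, 6), dtype=int)
        labels[0, :2] = 2  # 2-pixel orphan
        out = enforce_connectivity(labels, min_size=5)
        assert out.max() == 1

    def test_random_noise_yields_one_component_per_label(self, rng):
        labels = rng.integers(1, 6, size=(32, 32))
        out = enforce_connectivity(labels, min_size=4)
        _, ncomp = _components(out)
        assert ncomp == out.max()
        assert out.min() == 1


class TestFilterBackground:
    @pytest.fixture()
    def quadrant_map(self):
        labels = np.ones((40, 40), dtype=int)
        labels[:20, 20:] = 2
        labels[20:, :20] = 3
        labels[20:, 20:] = 4
        return labels

    def test_full_mask_keeps_all(self, quadrant_map):
        sp = filter_background_superpixels(quadrant_map, np.ones((40, 40), bool))
        assert sp.kept_labels == (1, 2, 3, 4)

    def test_empty_mask_keeps_none(self, quadrant_map):
        sp = filter_background_superpixels(quadrant_map, np.zeros((40, 40), bool))
        assert sp.kept_labels == () and sp.n_kept == 0

    def test_quadrant_mask_keeps_exactly_covered(self, quadrant_map):
        mask = np.zeros((40, 40), bool)
        mask[:20, 20:] = True  # quadrant 2
        mask[20:, :20] = True  # quadrant 3
        sp = filter_background_superpixels(quadrant_map, mask, 0.5)
        assert sp.kept_labels == (2, 3)

    def test_partition_conserved(self, quadrant_map):
        mask = np.zeros((40, 40), bool)
        mask[:25, :] = True
        sp = filter_background_superpixels(quadrant_map, mask, 0.5)
        assert sum(sp.per_label_pixel_count.values()) == 40 * 40

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_kept_set_shrinks_with_threshold(self, seed):
        rng = np.random.default_rng(seed)
        labels = enforce_connectivity(rng.integers(1, 8, size=(24, 24)), 1)
        mask = rng.random((24, 24)) < 0.5
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            kept = set(filter_background_superpixels(labels, mask, thr).kept_labels)
            if prev is not None:
                assert kept <= prev
            prev = kept
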