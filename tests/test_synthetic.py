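import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from dermasp import (
    SyntheticConfig,
    add_hair_overlay,
    compute_sp_features,
    generate_feature_table,
    generate_lesion_image,
)
from dermasp.synthetic import CLASS_DEFAULTS, FEATURE_COLUMNS, hair_raster


class TestGenerateLesionImage:
    def test_unperturbed_circle_mask_area(self):
        cfg = SyntheticConfig(border_irregularity=0.0, axis_ratio=1.0, seed=1)
        _, mask, _ = generate_lesion_image(cfg)
        expected = np.pi * cfg.lesion_radius_px**2
        assert abs(mask.sum() - expected) / expected < 0.05

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig.for_class("melanoma", seed=11)
        a = generate_lesion_image(cfg)
        b = generate_lesion_image(cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mask_single_4connected_component(self):
        for seed in range(8):
            _, mask, _ = generate_lesion_image(
                SyntheticConfig.for_class("melanoma", seed=seed)
            )
            _, n = ndimage.label(mask)  # default structure is 4-connectivity
            assert n == 1

    def test_melanoma_masks_more_eccentric_than_nevus(self):
        """Class effect sizes must be recoverable from the fitted ellipse."""
        eccs = {}
        for cls in ("nevus", "melanoma"):
            vals = [
                compute_sp_features(
                    generate_lesion_image(SyntheticConfig.for_class(cls, seed=s))[1]
                ).eccentricity
                for s in range(30)
            ]
            eccs[cls] = np.mean(vals)
        assert eccs["melanoma"] > eccs["nevus"]

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SyntheticConfig(lesion_radius_px=200)

    def test_class_defaults_ordering(self):
        nev, mel = CLASS_DEFAULTS["nevus"], CLASS_DEFAULTS["melanoma"]
        assert mel["border_irregularity"] > nev["border_irregularity"]
        assert mel["axis_ratio"] < nev["axis_ratio"]


class TestHairOverlay:
    def test_zero_hairs_identity(self, nevus_sample):
        img = nevus_sample[0]
        assert np.array_equal(add_hair_overlay(img, 0, 3, seed=1), img)

    def test_only_curve_pixels_differ(self, nevus_sample):
        img = nevus_sample[0]
        hairy = add_hair_overlay(img, 5, 3, seed=42)
        raster = hair_raster(img.shape[:2], 5, 3, 42)
        diff = (hairy != img).any(axis=-1)
        assert np.array_equal(hairy[~raster], img[~raster])
        assert diff[raster].all()

    def test_deterministic_geometry(self, nevus_sample):
        img = nevus_sample[0]
        assert np.array_equal(
            add_hair_overlay(img, 5, 3, seed=9), add_hair_overlay(img, 5, 3, seed=9)
        )


class TestFeatureTable:
    def test_shape_and_schema(self):
        df = generate_feature_table(3, 1.0, seed=0)
        assert len(df) == 6
        assert list(df.columns) == ["image_id", "sp_label", *FEATURE_COLUMNS, "class"]
        assert df["class"].value_counts().tolist() == [3, 3]

    def test_zero_separation_identical_distributions(self):
        """At separation 0 the class mean shift vanishes by construction."""
        from dermasp.synthetic import _SHIFT_DIR, _TABLE_SDS

        assert np.allclose(0.0 * _SHIFT_DIR * _TABLE_SDS, 0.0)
        df = generate_feature_table(2000, 0.0, seed=3)
        means = df.groupby("class")[FEATURE_COLUMNS].mean()
        # Same 6-D Gaussian: sample means agree to sampling error.
        z = (means.loc[0] - means.loc[1]).abs() / (_TABLE_SDS * np.sqrt(2 / 2000))
        assert (z < 4).all()

    def test_separability_monotone_in_separation(self):
        """Held-out RF accuracy must not decrease as separation grows."""
        from dermasp.dataset import SplitSpec, split_dataset, zscore_fit_transform
        from dermasp.models import build_spec, predict, train_model

        mean_acc = []
        for sep in (0.0, 1.0, 2.0, 4.0):
            accs = []
            for seed in range(5):
                df = generate_feature_table(200, sep, seed=seed)
                tr_raw, te_raw = split_dataset(df, SplitSpec(0.7, seed=seed))
                tr, te, _ = zscore_fit_transform(tr_raw, te_raw)
                model = train_model(build_spec("RF", seed=seed), tr, cv_folds=None)
                accs.append((predict(model, te) == te["class"].to_numpy()).mean())
            mean_acc.append(np.mean(accs))
        assert all(b >= a - 0.02 for a, b in zip(mean_acc, mean_acc[1:]))
        assert mean_acc[-1] > 0.9
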