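import numpy as np
import pytest

from dermasp import SyntheticConfig, apply_black_mask, generate_lesion_image


@pytest.fixture(scope="session")
def nevus_sample():
    """One hair-free nevus image with its ground-truth mask."""
    img, mask, label = generate_lesion_image(
        SyntheticConfig.for_class("nevus", seed=7, n_hairs=0)
    )
    return img, mask, label


@pytest.fixture(scope="session")
def melanoma_sample():
    img, mask, label = generate_lesion_image(
        SyntheticConfig.for_class("melanoma", seed=7, n_hairs=0)
    )
    return img, mask, label


@pytest.fixture(scope="session")
def masked_nevus(nevus_sample):
    """Nevus image with the background blackened from the truth mask."""
    img, mask, _ = nevus_sample
    return apply_black_mask(img, mask), mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
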