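import numpy as np
import pytest

import hairbench as hb


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_mask_config():
    """Benchmark mask geometry scaled to a 64x64 canvas (256x256 working)."""
    return hb.MaskGenConfig.scaled_to((64, 64))


@pytest.fixture(scope="session")
def skin_image():
    cfg = hb.SyntheticSkinConfig(canvas_size=(64, 64),
                                 lesion_radius_range=(10.0, 20.0))
    return hb.generate_synthetic_skin(cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def paired_sample(small_mask_config, skin_image):
    rng = np.random.default_rng(11)
    mask = hb.generate_mask(small_mask_config, rng)
    return hb.composite(skin_image, mask, hb.CompositeConfig(), rng)
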