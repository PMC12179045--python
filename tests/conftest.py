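import numpy as np
import pytest

from vesselkd.data import load_dataset
from vesselkd.models import UNetConfig
from vesselkd.synthetic import SyntheticSceneParams, make_dataset


@pytest.fixture(scope="session")
def tiny_params():
    """Easy-regime scene parameters small enough for fast unit tests."""
    return SyntheticSceneParams(
        image_height=32,
        image_width=32,
        n_trees=1,
        branch_depth=2,
        vessel_contrast=0.9,
        background_noise_sd=0.01,
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_params):
    """Four train / one val / two test triplets at 32x32."""
    root = make_dataset(4, 1, 2, tiny_params, tmp_path_factory.mktemp("ds"))
    return load_dataset(root)


@pytest.fixture(scope="session")
def tiny_unet_cfg():
    return UNetConfig(in_channels=1, base_width=8, depth=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
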