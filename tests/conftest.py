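import numpy as np
import pytest

from ftsgan.image_io import GrayImage, ImagePair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_pair(rng):
    v = GrayImage(rng.uniform(0.0, 1.0, (16, 16)))
    i = GrayImage(rng.uniform(0.0, 1.0, (16, 16)))
    return ImagePair(visible=v, infrared=i, pair_id="fixture")
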