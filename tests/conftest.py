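import numpy as np
import pytest

from histopet.segmentation import BinaryMask, ProbabilityMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.3, pixel_size_um=10.0) -> BinaryMask:
    return BinaryMask((rng.random(shape) < p).astype(np.uint8), pixel_size_um)


def random_probability_map(rng, shape, pixel_size_um=10.0) -> ProbabilityMap:
    return ProbabilityMap(rng.random(shape), pixel_size_um)
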