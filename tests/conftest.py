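import numpy as np
import pytest

from geofilter import ImageGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_image(seed: int, shape=(7, 7), channels: int = 1, lo=0.0, hi=255.0) -> ImageGrid:
    """Seeded uniform-random test image."""
    r = np.random.default_rng(seed)
    if channels == 1:
        return ImageGrid(r.uniform(lo, hi, shape))
    return ImageGrid(r.uniform(lo, hi, (*shape, channels)))
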