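import warnings

import numpy as np
import pytest

from ecasii import LabelMap, SceneSpec, SpectralImage, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return SpectralImage(rng.random((16, 16, 5)))


@pytest.fixture
def halfplane_labels():
    """Two classes split by a vertical line at column 5 (10x10)."""
    lab = np.ones((10, 10), dtype=int)
    lab[:, 5:] = 2
    return LabelMap(lab)


@pytest.fixture
def small_scene():
    """A 24x24 three-band five-class scene with mild noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_scene(
            SceneSpec(N=5, Dmax=0.3, rmax=0.06, smin=0.2, smax=0.5,
                      height=24, width=24, bands=3, seed=42)
        )
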