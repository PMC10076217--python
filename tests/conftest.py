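import numpy as np
import pytest

from panorf import scenes


@pytest.fixture(scope="session")
def homogeneous_images():
    """Statistically homogeneous 1/f panoramas for patch sampling."""
    return [scenes.generate_panorama(scenes.SceneParams.homogeneous(seed=s))
            for s in range(30)]


@pytest.fixture(scope="session")
def default_images():
    """Panoramas with the elevation-dependent power structure."""
    return [scenes.generate_panorama(scenes.SceneParams(seed=s))
            for s in range(50)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
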