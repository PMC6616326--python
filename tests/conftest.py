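import numpy as np
import pytest

from vigorscan import SceneParams, generate_seedling_image


@pytest.fixture(scope="session")
def default_scene():
    """One rendered seedling scene with ground truth (seed 1, defaults)."""
    return generate_seedling_image(1)


@pytest.fixture(scope="session")
def noiseless_scene():
    return generate_seedling_image(3, SceneParams(noise_rate=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_masks(n: int, shape=(16, 16), p=0.4, seed=0):
    """n random boolean masks for filter-oracle comparisons."""
    rng = np.random.default_rng(seed)
    return [rng.random(shape) < p for _ in range(n)]
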