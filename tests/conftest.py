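import numpy as np
import pytest

from erytex.simulate import SimulationConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 3-subject study at reduced image size, shared across tests."""
    out = tmp_path_factory.mktemp("study")
    config = SimulationConfig(n_subjects=3, image_size=64, seed=42)
    paths = generate_study(config, out)
    return {"config": config, "dir": out, **paths}


def random_masked_image(rng, shape=(16, 16)):
    """Random grey image plus a random mask guaranteed to contain a valid pair."""
    image = rng.integers(0, 256, size=shape)
    mask = rng.random(shape) < 0.5
    mask[shape[0] // 2, 0:2] = True  # ensure at least one horizontal pair
    return image, mask
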