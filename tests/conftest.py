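import numpy as np
import pytest

from mwdhseg import default_scenarios, double_haar_bank, generate_phantom


@pytest.fixture(scope="session")
def bank():
    return double_haar_bank()


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios(rng_seed=0)


@pytest.fixture(scope="session")
def baseline_case(scenarios):
    return generate_phantom(scenarios["baseline"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def square_image():
    """Noiseless two-value image: 20x20 object square on a flat background."""
    img = np.full((64, 64), 10.0)
    img[20:40, 22:42] = 50.0
    truth = np.zeros((64, 64), dtype=np.uint8)
    truth[20:40, 22:42] = 1
    return img, truth
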