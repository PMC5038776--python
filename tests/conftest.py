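import numpy as np
import pytest

from scmfuse import fixture_suite


@pytest.fixture(scope="session")
def fixtures() -> dict:
    return fixture_suite()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160915)


def random_u8(rng: np.random.Generator, shape=(16, 16)) -> np.ndarray:
    return rng.integers(0, 256, size=shape, dtype=np.uint8)
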