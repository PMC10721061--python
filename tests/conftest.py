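import numpy as np
import pytest

from phaserestore import Grid


@pytest.fixture
def unit64() -> Grid:
    return Grid.unit_square(64)


@pytest.fixture
def unit256() -> Grid:
    return Grid.unit_square(256)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240614)
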