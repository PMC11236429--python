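import numpy as np
import pytest

from soilsubcomm import OtuTable, SampleMetadata, simulate_metadata


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [10, 0, 3, 1, 0],
            [5, 5, 0, 2, 0],
            [0, 8, 2, 1, 1],
        ]
    )
    return OtuTable(["s1", "s2", "s3"], [f"o{i}" for i in range(5)], counts)


@pytest.fixture
def meta46():
    return simulate_metadata(46, 7, seed=11)


@pytest.fixture
def random_table(rng):
    counts = rng.integers(0, 40, size=(12, 80))
    counts[:, 0] += 1  # keep every sample nonzero
    return OtuTable(
        [f"s{i}" for i in range(12)], [f"o{j}" for j in range(80)], counts
    )
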