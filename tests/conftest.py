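import numpy as np
import pytest

from clrda import CountTable, SampleFrame, SimScenario, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array([
        [10, 0, 5, 3],
        [0, 20, 1, 0],
        [100, 50, 80, 60],
    ])
    return CountTable(counts, ["tA", "tB", "tC"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def binary_frame():
    return SampleFrame(["s1", "s2", "s3", "s4"], np.array([0.0, 0.0, 1.0, 1.0]))


@pytest.fixture(scope="session")
def s0_dataset():
    """One baseline simulated dataset shared by read-only tests."""
    return simulate(SimScenario(seed=11))
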