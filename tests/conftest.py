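import numpy as np
import pytest

from isoniche import load_reference_summaries
from isoniche.simulate import simulate_from_summaries


@pytest.fixture(scope="session")
def summaries():
    return load_reference_summaries()


@pytest.fixture(scope="session")
def records(summaries):
    """One seeded replicate-level realisation of the packaged summary table."""
    return simulate_from_summaries(summaries, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
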