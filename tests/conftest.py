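import numpy as np
import pytest

from traitlv import (
    SyntheticScenario,
    generate_axes,
    random_demography,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One forward-simulated dataset under the default study conditions."""
    return simulate_dataset(SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def small_axes():
    return generate_axes(20, 3, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
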