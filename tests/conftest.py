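import numpy as np
import pytest

from ppiface import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def small_dataset():
    """12 short chains with the default planted signal; shared across tests."""
    return generate_fixture(
        FixtureConfig(n_chains=12, chain_length_range=(40, 60), seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20100728)
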