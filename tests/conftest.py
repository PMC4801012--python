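import numpy as np
import pytest

from wolfallee.landscape import LandscapeGeneratorParams, generate_landscape


@pytest.fixture(scope="session")
def default_landscape():
    """One default synthetic landscape shared across the suite."""
    return generate_landscape(LandscapeGeneratorParams(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
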