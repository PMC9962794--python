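import numpy as np
import pytest

import chansyn as cs


@pytest.fixture(scope="session")
def example_cat():
    """The curated channel catalog shipped with the package."""
    return cs.example_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Minimal catalog with one anion + one cation gene per transmitter."""
    return cs.synthetic_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230215)
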