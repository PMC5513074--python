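import numpy as np
import pytest

from riboxi import landscape as lnd


@pytest.fixture(scope="session")
def small_reference():
    return lnd.make_reference(2000, gc_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def small_landscape(small_reference):
    return lnd.plant_sites(small_reference, density=1 / 60, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
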