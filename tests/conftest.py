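import numpy as np
import pytest

from ordmi import GenerativeSpec, simulate_full_table


@pytest.fixture
def rng():
    return np.random.default_rng(20230509)


@pytest.fixture(scope="session")
def default_spec():
    return GenerativeSpec()


@pytest.fixture(scope="session")
def c_map():
    return {v: 4 for v in ("y", "m1", "m2", "m3")}


@pytest.fixture(scope="session")
def small_table():
    """One N=50 complete panel under the default generative spec."""
    return simulate_full_table(GenerativeSpec(), np.random.default_rng(7))
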