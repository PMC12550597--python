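import numpy as np
import pytest

from reactbo import fixture_catalyst_set, make_benchmark


@pytest.fixture(scope="session")
def catalysts6():
    return fixture_catalyst_set(6)


@pytest.fixture(scope="session")
def amidation():
    return make_benchmark("amidation_sim")


@pytest.fixture(scope="session")
def api():
    return make_benchmark("api_reaction")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
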