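import numpy as np
import pytest

from pssem import simulation


@pytest.fixture(scope="session")
def design_sigma():
    return simulation.design_sigma()


@pytest.fixture(scope="session")
def design_model():
    return simulation.design_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def one_factor_model():
    from pssem.sem_engine import parse_model
    return parse_model("F1 =~ y1 + y2 + y3 + y4")
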