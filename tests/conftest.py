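import numpy as np
import pytest
from hypothesis import settings

from maillard_kinetics import RateConstants, build_model_system, table1_scenario

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def lys_spec():
    return build_model_system("Lys/Glu", 170)


@pytest.fixture
def trp_spec():
    return build_model_system("Trp/Glu", 170)


@pytest.fixture
def com_scenario():
    return table1_scenario("Com-Glu-170")


@pytest.fixture
def k_zero():
    return RateConstants.zeros()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
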