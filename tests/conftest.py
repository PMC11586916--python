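import numpy as np
import pytest

from crsim import CensoringModel, scenario_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def scenario1():
    return scenario_spec(1, 200, 200)


@pytest.fixture
def scenario1_random():
    return scenario_spec(1, 200, 200, CensoringModel.exponential(0.001))


@pytest.fixture
def exp_families():
    return ["exponential"] * 3


@pytest.fixture
def gw_families():
    return ["gompertz", "gompertz", "weibull"]
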