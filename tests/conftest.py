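import numpy as np
import pytest

from cryor import synthgen


@pytest.fixture(scope="session")
def rec20_config():
    return synthgen.load_scenario("cryor1_rec_20C")


@pytest.fixture(scope="session")
def fsta105_config():
    return synthgen.load_scenario("cryor1_fsta_ph10p5")


@pytest.fixture(scope="session")
def osc_config():
    return synthgen.load_scenario("cryor1_osc_ph3p5")


@pytest.fixture(scope="session")
def titration_config():
    return synthgen.load_scenario("cryor1_titration")


@pytest.fixture(scope="session")
def ephys_config():
    return synthgen.load_scenario("cryor1_ephys")


@pytest.fixture(scope="session")
def ephys_traces(ephys_config):
    return synthgen.make_current_traces(ephys_config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
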