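import numpy as np
import pandas as pd
import pytest

from fluxomix.synthetic_data import (
    FermentationScenario,
    make_synthetic_expression,
    make_synthetic_pools,
    make_toy_model,
    simulate_fermentation,
)


@pytest.fixture(scope="session")
def chain_model():
    return make_toy_model("chain")


@pytest.fixture(scope="session")
def diamond_model():
    return make_toy_model("diamond")


@pytest.fixture(scope="session")
def core_model():
    return make_toy_model("core")


@pytest.fixture(scope="session")
def noise_free_fermentation(core_model):
    scenario = FermentationScenario(noise_sd=0.0, tolerance=0.0)
    return simulate_fermentation(core_model, scenario)


@pytest.fixture(scope="session")
def pools_seed1():
    return make_synthetic_pools(seed=1)


@pytest.fixture(scope="session")
def expression_seed1():
    return make_synthetic_expression(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
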