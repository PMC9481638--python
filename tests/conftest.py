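import numpy as np
import pandas as pd
import pytest

from medwas.pregnancy import default_dictionary
from medwas.simulate import SimulationConfig, generate_population


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_dyads=400,
        n_drugs=5,
        n_phecodes=8,
        baseline_prevalence=0.08,
        exposure_prevalence=0.15,
        true_effects=[(0, 0, 4.0)],
        seed=2024,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return generate_population(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
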