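import logging

import numpy as np
import pytest

from flowpred import PopulationParams
from flowpred.power import simulate_experiment

# the exclusion filter logs an expected warning when head bins are absent
logging.getLogger("flowpred.preprocessing").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pop() -> PopulationParams:
    """Default population parameters (the study conditions)."""
    return PopulationParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(pop):
    """One small simulated dual-task cohort shared across tests."""
    return simulate_experiment(
        n_participants=8, repetitions=5, pest_band=(30, 37), pop=pop,
        seed=np.random.SeedSequence(20240117),
    )
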