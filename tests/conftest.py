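import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from explorebandit import TaskConfig, Weights, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    return TaskConfig(n_subjects=2, seed=101)


@pytest.fixture(scope="session")
def human_scale_weights() -> Weights:
    # weights at the scale typically recovered from human subjects
    return Weights(w1=0.166, w2=0.175, w3=0.005)


@pytest.fixture(scope="session")
def sim_data(small_config, human_scale_weights) -> pd.DataFrame:
    return simulate_dataset(small_config, "hybrid", human_scale_weights)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
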