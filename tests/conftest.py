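import numpy as np
import pytest

from isletsim import ModelParams, ScenarioConfig


@pytest.fixture
def params() -> ModelParams:
    """Default (calibrated) parameter set."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario() -> ScenarioConfig:
    """Desk-scale scenario: a handful of cells, short horizon."""
    return ScenarioConfig(islet_radius=6.0, t_end=30.0, immunity="strong",
                          n_tcells_weak=5, seed_cancer_time=10.0, seed=7)
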