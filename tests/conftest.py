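import numpy as np
import pytest

from biogaskit import case_study
from biogaskit.synthetic_data import SyntheticExperimentConfig, simulate_experiment


@pytest.fixture
def case_matrix():
    """The bundled food-waste pretreatment decision matrix (6 x 5)."""
    return case_study.decision_matrix()


@pytest.fixture
def noise_free_experiment():
    """Synthetic triplicate experiment with zero measurement noise."""
    config = SyntheticExperimentConfig(noise_sd_fraction=0.0, seed=7)
    bottles, truth = simulate_experiment(config)
    return config, bottles, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
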