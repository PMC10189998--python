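import numpy as np
import pytest

from thermoallo import (CARABID_PARAMS, NoiseModel, StudyDesign,
                        generate_speed_dataset)


@pytest.fixture(scope="session")
def carabid_truth():
    """Published parameter estimates used as simulation ground truth."""
    return CARABID_PARAMS


@pytest.fixture(scope="session")
def noiseless_records(carabid_truth):
    """125 records lying exactly on the allometric-thermal surface."""
    return generate_speed_dataset(StudyDesign(seed=7), carabid_truth,
                                  NoiseModel(sigma=0.0))


@pytest.fixture(scope="session")
def noisy_records(carabid_truth):
    """Default study design with log-normal scatter (sigma_log = 0.30)."""
    return generate_speed_dataset(StudyDesign(seed=11), carabid_truth,
                                  NoiseModel(sigma=0.30))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
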