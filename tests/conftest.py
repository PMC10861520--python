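import numpy as np
import pytest

from wearra import experiments as ex
from wearra.config import default_config


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=7)


@pytest.fixture(scope="session")
def study_cfg():
    """Default study conditions: 30 HC / 13 RA-mod / 15 RA-sev, 14 days."""
    return ex.ExperimentConfig(seed=7)


@pytest.fixture(scope="session")
def study_features(study_cfg):
    """Fully simulated default study with daily feature tables (computed once)."""
    return ex.prepare_study(study_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
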