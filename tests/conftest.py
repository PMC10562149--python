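import numpy as np
import pytest

from ntcp_semisup.cohort import ampute, generate_cohort, mask_labels
from ntcp_semisup.config import development_config, validation_config
from ntcp_semisup.impute import chained_impute


@pytest.fixture(scope="session")
def dev_config():
    return development_config()

@pytest.fixture(scope="session")
def val_config():
    return validation_config()


@pytest.fixture(scope="session")
def dev_big():
    """Large development cohort for distributional checks."""
    return generate_cohort(development_config(n=100_000), seed=11)


@pytest.fixture(scope="session")
def dev_cohort(dev_config):
    """Complete 750-patient development cohort."""
    return generate_cohort(dev_config, seed=21)


@pytest.fixture(scope="session")
def dev_masked(dev_config, dev_cohort):
    """Development cohort after amputation, single imputation and masking of
    40 outcomes: the input state of the modeling experiments."""
    amp = ampute(dev_cohort, dev_config.missing_rates, seed=22)
    dev = chained_impute(amp, m=1, sweeps=5, seed=23).cohorts[0]
    return mask_labels(dev, 40, seed=24)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
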