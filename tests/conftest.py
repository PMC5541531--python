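import numpy as np
import pytest

from carnrange.model import CovariateSpec
from carnrange.synthetic import SimConfig, fixture_config, make_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """The 20x40-cell synthetic world used across unit tests."""
    return make_dataset(fixture_config(), seed=0)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic world (120x240 fine cells)."""
    return make_dataset(SimConfig(), seed=11)


def covariate_specs():
    """Model-side transform specs matching the synthetic covariates."""
    return [
        CovariateSpec("rural_pop_density", units="people/km^2", transform="log1p"),
        CovariateSpec("cattle_density", units="cattle/km^2", transform="log1p"),
        CovariateSpec("cropland", units="%", transform="none"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
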