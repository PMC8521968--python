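import numpy as np
import pytest

from bayespta import (
    AlphaTable,
    GPComponent,
    MixtureModel,
    default_population,
)


@pytest.fixture(scope="session")
def population():
    return default_population()


@pytest.fixture(scope="session")
def population_model(population):
    """The default population's own GP mixture prior (oracle model)."""
    return population.prior_model()


@pytest.fixture()
def simple_component():
    """A single mild-slope component with moderate uncertainty."""
    return GPComponent((30.0, 1.0, 0.0, 0.0), 100.0, 4.0)


@pytest.fixture()
def single_component_model(simple_component):
    return MixtureModel([simple_component], AlphaTable.constant([1.0]), sigma_p=5.0)


@pytest.fixture()
def two_component_model():
    comps = [
        GPComponent((20.0, 0.0, 0.0, 0.0), 64.0, 6.0),
        GPComponent((50.0, 2.0, 0.0, 0.0), 100.0, 4.0),
    ]
    return MixtureModel(comps, AlphaTable.constant([0.4, 0.6]), sigma_p=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
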