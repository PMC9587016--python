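import numpy as np
import pytest

from mixedmeal import (FitConfig, NoiseModel, SubjectSpec, default_parameters,
                       design, fit, generate_response, preset)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def subject():
    return SubjectSpec()


@pytest.fixture(scope="session")
def nutritech_fixture():
    """Noiseless NutriTech-design response from the NutriTech population
    preset (75 g glucose / 60 g TG meal, 6 samples per metabolite)."""
    return generate_response(design("nutritech"), preset("nutritech_population"),
                             noise=NoiseModel.noiseless(), seed=1)


@pytest.fixture(scope="session")
def metflex_fixture():
    """Noiseless MetFlex-design response from the MetFlex population preset
    (10 glucose/insulin samples, 7 TG/NEFA samples)."""
    return generate_response(design("metflex"), preset("metflex_population"),
                             noise=NoiseModel.noiseless(), seed=1)


@pytest.fixture(scope="session")
def nutritech_fit(nutritech_fixture):
    """Regularized multi-start fit of the default free set to the noiseless
    NutriTech fixture (shared by the identifiability tests)."""
    return fit(nutritech_fixture, FitConfig(n_starts=25, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
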