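import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from physiopop import load_parameters

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def uk_male_white():
    return load_parameters(("UK", "male", "White"))


@pytest.fixture(scope="session")
def uk_female_white():
    return load_parameters(("UK", "female", "White"))


@pytest.fixture(scope="session")
def us_nbh_female():
    return load_parameters(("US", "female", "Non-Black Hispanic"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def zero_sigma(params):
    """A copy of a parameter set with every dispersion parameter set to 0.

    In this degenerate limit every sampled quantity equals its location,
    which lets the whole pipeline be checked against closed-form
    evaluation of the model formulas.
    """
    anthro = dataclasses.replace(params.anthro, height_sigma=0.0, logbm_sigma=0.0)
    co = dataclasses.replace(params.co, sigma=0.0)
    organs = {
        name: dataclasses.replace(model, sigma=0.0, flow_sigma=0.0)
        for name, model in params.organs.items()
    }
    return dataclasses.replace(params, anthro=anthro, co=co, organs=organs)
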