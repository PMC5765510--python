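"""Shared fixtures: default constants, models and one cached simulation of
the standard cascade (several tests interrogate the same trajectory)."""

import numpy as np
import pytest

from gdpman import (
    CascadeModel,
    RateParameters,
    build_model,
    simulate,
    standard_cascade_design,
)


@pytest.fixture(scope="session")
def defaults() -> RateParameters:
    return RateParameters()


@pytest.fixture(scope="session")
def cascade_model(defaults) -> CascadeModel:
    return build_model("cascade", defaults)


@pytest.fixture(scope="session")
def standard_design():
    return standard_cascade_design()


@pytest.fixture(scope="session")
def cascade_result(cascade_model, standard_design):
    return simulate(cascade_model, standard_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
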