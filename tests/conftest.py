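import numpy as np
import pytest
from hypothesis import settings

from dphp_pbpk import model
from dphp_pbpk.parameters import ExposureScenario, build_subject_from_flat, default_priors

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scen_default() -> ExposureScenario:
    """Volunteer-A style scenario: 83 kg, 0.717 mg/kg, 48 h horizon."""
    return ExposureScenario(dose=0.717, BW=83.0, t_end=48.0)


@pytest.fixture(scope="session")
def subject_default(scen_default):
    return build_subject_from_flat({}, scen_default)


@pytest.fixture(scope="session")
def result_default(subject_default, scen_default) -> model.SimulationResult:
    """Reference (adaptive) simulation at packaged defaults."""
    return model.simulate(subject_default, scen_default)


@pytest.fixture(scope="session")
def result_rk4(subject_default, scen_default) -> model.SimulationResult:
    return model.simulate(subject_default, scen_default, engine="rk4")


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
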