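import numpy as np
import pytest

from posturemep import PopulationConfig
from posturemep.synth import sample_subject


@pytest.fixture(scope="session")
def population() -> PopulationConfig:
    return PopulationConfig()


@pytest.fixture(scope="session")
def subject_model(population):
    """One representative subject drawn from the default population."""
    return sample_subject(population, "sub-01", np.random.SeedSequence(42))


@pytest.fixture()
def quiet_model(subject_model):
    """A copy of the subject with deterministic amplitudes: no background
    noise, no trial-to-trial MEP variability."""
    import copy

    m = copy.deepcopy(subject_model)
    m.background_rms = {k: 0.0 for k in m.background_rms}
    m.mep_cv = 0.0
    return m


@pytest.fixture()
def alternating_model(subject_model):
    """Deterministic +/-RMS carrier: rectified traces equal RMS x envelope."""
    import copy

    m = copy.deepcopy(subject_model)
    m.carrier = "alternating"
    m.mep_cv = 0.0
    return m
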