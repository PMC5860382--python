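import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spotna24.cohort import generate_study
from spotna24.config import CohortConfig, load_coefficients
from spotna24.equations import predict_all
from spotna24.processing import process_study
from spotna24.types import ParticipantProfile

settings.register_profile(
    "suite", derandomize=True, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lib():
    return load_coefficients()


@pytest.fixture
def profile():
    """Reference participant: 60-year-old white man, 80 kg, 170 cm."""
    return ParticipantProfile(
        id="P0", sex="male", race="white", age=60.0, height=170.0,
        weight=80.0, bmi=80.0 / 1.7 ** 2)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(CohortConfig(n_participants=80), seed=11)


@pytest.fixture(scope="session")
def processed(small_study, lib):
    specimens, daily = process_study(
        small_study.voids, small_study.collections, small_study.profiles, lib)
    return specimens, daily


@pytest.fixture(scope="session")
def predictions(processed, small_study, lib):
    specimens, _ = processed
    return predict_all(specimens, small_study.profiles, lib)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
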