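import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ocusim as oc
from ocusim.eye import FocusBoundaryWarning, mean_biometry

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FocusBoundaryWarning)


@pytest.fixture(scope="session")
def mean_pre_eye_2mm():
    """Spectacle-corrected mean-parameter pre-operative eye, 2-mm pupil."""
    return oc.build_eye(mean_biometry("pre"), stop_diameter=2.0, focus=True)


@pytest.fixture(scope="session")
def mean_post_eye_2mm():
    """Retina-shift-focused mean-parameter post-operative eye, 2-mm pupil."""
    return oc.build_eye(mean_biometry("post"), stop_diameter=2.0, focus=True)


@pytest.fixture(scope="session")
def small_cohort():
    return oc.sample_cohort(oc.CohortConfig(n=20, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
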