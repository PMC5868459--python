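import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from retroprobe import DesignSpec, GenerativeParams, simulate_cohort, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def e1_session():
    """One simulated E1 subject with the default (effectful) truth."""
    return simulate_session(DesignSpec.e1(), GenerativeParams(), seed=101, subject_id="S01")


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated E1 subjects; enough for every pipeline cell."""
    return simulate_cohort(DesignSpec.e1(), GenerativeParams(), n_subjects=6, seed=42)
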