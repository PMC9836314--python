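import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import spatialhear as sh
from spatialhear import synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Record-level cohort with the default (effectful) generator."""
    return sh.simulate_cohort(n_subjects=6, seed=20240901)


@pytest.fixture(scope="session")
def cells(cohort):
    return sh.summarize_cells(cohort.trials, cohort.responses)


@pytest.fixture(scope="session")
def speaker_array():
    return sh.build_speaker_array(15.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
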