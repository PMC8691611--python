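import numpy as np
import pytest

from actimetry import (EpochParams, ScenarioParams, build_datasets,
                       generate_cohort, generate_recording)

EP = EpochParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def short_recording():
    """One hour of the default wrist scenario (fixed seed)."""
    rec, truth = generate_recording(ScenarioParams(duration_s=3600.0, seed=7))
    return rec, truth


@pytest.fixture(scope="session")
def short_datasets(short_recording):
    rec, _ = short_recording
    return build_datasets(rec, include_hfen=True)


@pytest.fixture(scope="session")
def cohort():
    """The default 3-subject, 12 h synthetic cohort (fixed master seed)."""
    return generate_cohort(3, seed=0)


@pytest.fixture(scope="session")
def cohort_datasets(cohort):
    return [build_datasets(rec, include_hfen=True) for rec in cohort]
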