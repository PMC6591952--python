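import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fcmethods as fc

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    return fc.SyntheticSpec(
        n_sites=2, per_site_n=[(12, 12), (12, 12)], n_regions=45,
        n_timepoints=100, tr_seconds=2.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return fc.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_profile(small_spec):
    profile, _ = fc.generate_reference_profile(
        small_spec, n_reference_subjects=20, n_timepoints=120)
    return profile


@pytest.fixture(scope="session")
def paper_atlas():
    return fc.make_synthetic_atlas(361, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
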