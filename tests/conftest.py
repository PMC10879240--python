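import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import raftscape as rs
from raftscape.lipid_core import FattyAcidProfile, LipidClassProfile, SubjectRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_fa():
    """Five-species profile whose totals are a hand summation."""
    return FattyAcidProfile(
        "toy",
        {"16:0": 30.0, "18:0": 20.0, "18:1n-9": 25.0, "20:4n-6": 15.0, "22:6n-3": 10.0},
    )


@pytest.fixture
def toy_lc():
    return LipidClassProfile(
        "toy",
        {"PC": 20.0, "PE": 20.0, "PS": 10.0, "PI": 5.0, "PG": 5.0,
         "SM": 10.0, "SULF": 6.0, "OTHER_SL": 4.0, "CHO": 16.0, "SE": 4.0},
    )


@pytest.fixture
def toy_record(toy_fa, toy_lc):
    return SubjectRecord("toy", "NSL", toy_fa, toy_lc)


@pytest.fixture(scope="session")
def small_cohort():
    """Default conditions at a modest size for fast pipeline tests."""
    return rs.generate_cohort(rs.default_config(n_nsl=12, n_als=10, seed=1))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Default conditions at the recovery scale (200 per group)."""
    return rs.generate_cohort(rs.default_config(n_nsl=200, n_als=200, seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
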