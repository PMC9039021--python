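import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from raredrop import BUILTIN_PROFILES, packaged_cohort_path, read_cohort_table
from raredrop.calling import WellClassification

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def qx200():
    return BUILTIN_PROFILES["qx200"]


@pytest.fixture
def qiacuity():
    return BUILTIN_PROFILES["qiacuity"]


@pytest.fixture(scope="session")
def cohort_records():
    return read_cohort_table(packaged_cohort_path())


@pytest.fixture
def rng():
    return np.random.default_rng(20220412)


def make_well(n_fam: int, n_hex: int, n_double: int = 0, n_total: int = 20_000):
    """Build a WellClassification from channel counts (helper for rule tests)."""
    return WellClassification(
        n_total=n_total,
        n_fam_pos=n_fam,
        n_hex_pos=n_hex,
        n_double_pos=n_double,
        n_double_neg=n_total - n_fam - n_hex + n_double,
    )
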