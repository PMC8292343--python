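import pytest

from twohitscan.cohort import CohortConfig, generate_cohort
from twohitscan.fixtures import study_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return study_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort exercising every planted structure quickly."""
    cfg = CohortConfig(seed=11, n_patients=24, n_ls_carriers=6, n_reference=30)
    return cfg, generate_cohort(cfg)
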