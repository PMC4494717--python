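import pytest

from luscore.cohort import CohortParams, generate_cohort
from luscore.fixtures import study_fixtures


@pytest.fixture(scope="session")
def fixtures_bundle():
    return study_fixtures()


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized synthetic cohort (106 cases + 25 controls), fixed seed."""
    return generate_cohort(CohortParams(seed=1))


@pytest.fixture(scope="session")
def large_case_cohort():
    """Large all-case cohort for parameter-recovery and calibration checks."""
    return generate_cohort(CohortParams(n_cases=5000, n_controls=0, seed=1))
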