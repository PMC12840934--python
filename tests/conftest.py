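import pytest

from basalwatch import CohortSpec, simulate


@pytest.fixture(scope="session")
def small_spec():
    """Small cohort with moderate missingness for fast structural tests."""
    return CohortSpec(n_residents=20, n_days=200, seed=7, missing_rate=0.5)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate(small_spec)


@pytest.fixture(scope="session")
def dense_spec():
    """Fully observed cohort — isolates logic from missingness."""
    return CohortSpec(n_residents=15, n_days=150, seed=3, missing_rate=0.0)


@pytest.fixture(scope="session")
def dense_cohort(dense_spec):
    return simulate(dense_spec)
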