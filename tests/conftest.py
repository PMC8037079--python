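import pytest

from gertality import GeneratorConfig, generate_cohort, generate_worked_fixture

#: Seed used for the large simulated cohorts exercised across the suite.
DEFAULT_SEED = 20210325


@pytest.fixture
def worked_cohort():
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def default_cohort_50k():
    """Default-parameter synthetic cohort, shared across tests for speed."""
    return generate_cohort(GeneratorConfig(n=50_000, seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def clean_cohort_50k():
    """Same size, missingness disabled: for parameter-recovery checks."""
    return generate_cohort(
        GeneratorConfig(
            n=50_000,
            seed=DEFAULT_SEED,
            missing_gcs=0.0,
            missing_asa=0.0,
            missing_sbp=0.0,
        )
    )
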