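import pytest

from exophen import run_pipeline, reference_cohort_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 89-participant cohort mirroring the published
    cross-tabulation, shared across the suite (read-only)."""
    return reference_cohort_fixture()


@pytest.fixture(scope="session")
def pipeline_result(fixture_cohort):
    """Full pipeline output on the fixture cohort."""
    return run_pipeline(fixture_cohort,
                        panels=fixture_cohort.panels,
                        pathogenicity=fixture_cohort.pathogenicity)
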