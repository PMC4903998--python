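import pytest

from pidtriage import (
    FilterConfig,
    default_cohort_config,
    fixture_panel,
    generate_cohort,
    load_paper_fixture,
    run_pipeline,
)


@pytest.fixture(scope="session")
def paper():
    """The packaged published-tables cohort."""
    return load_paper_fixture()


@pytest.fixture(scope="session")
def paper_result(paper):
    """Full pipeline run over the packaged cohort, default thresholds."""
    return run_pipeline(paper.callset, paper.pedigree, paper.panel)


@pytest.fixture()
def cfg():
    return FilterConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient synthetic cohort exercising every scenario kind."""
    config = default_cohort_config(fixture_panel(), seed=11, n_patients=30)
    return generate_cohort(config), config
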