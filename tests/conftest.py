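import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def survey_fixture():
    """The reconstructed 53-gene survey replicon with its truth manifest."""
    from ambistart.tables import table_fixture

    return table_fixture()


@pytest.fixture(scope="session")
def survey_report(survey_fixture):
    """(rows, overlaps, calls) of the full pipeline on the survey replicon."""
    from ambistart.report import build_report

    return build_report(survey_fixture.genome)


@pytest.fixture(scope="session")
def suite_genome():
    """Default plant suite on a circular replicon with an origin-spanning window."""
    from ambistart.synthetic import default_plant_suite, generate_synthetic_genome

    return generate_synthetic_genome(
        default_plant_suite(),
        n_decoys=12,
        seed=11,
        topology="circular",
        origin_in_upstream_of="rep10",
    )
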