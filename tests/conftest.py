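import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def canonical():
    from limbcost.synthetic import canonical_cohort

    return canonical_cohort()


@pytest.fixture(scope="session")
def canonical_scenario():
    from limbcost.costing import canonical_scenario

    return canonical_scenario()


@pytest.fixture(scope="session")
def printed_scenario():
    from limbcost.costing import printed_scenario

    return printed_scenario()


@pytest.fixture(scope="session")
def canonical_report(canonical, canonical_scenario):
    from limbcost.costing import cohort_total_cost

    return cohort_total_cost(canonical, canonical_scenario)


@pytest.fixture(scope="session")
def average_patient_report(canonical_scenario):
    """Cohort report for the representative modelled patient: a single
    transtibial amputee under the canonical scenario."""
    from limbcost.costing import cohort_total_cost
    from limbcost.registry import AmputationEvent, AmputationLevel, CasualtyRecord

    rec = CasualtyRecord(
        "avg",
        2010,
        (AmputationEvent("avg", AmputationLevel.TRANSTIBIAL, 2010),),
    )
    return cohort_total_cost([rec], canonical_scenario)
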