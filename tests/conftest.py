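import pytest

from sdqchange import AttritionConfig, CohortConfig, StudentRecord, SubscaleScores, generate


def make_record(
    id="S1",
    t1=(2, 2, 3, 1, 0),
    t2=(2, 2, 3, 1, 0),
    **overrides,
) -> StudentRecord:
    """Hand-built record with sensible defaults for targeted cases."""

    def scores(tup):
        if tup is None:
            return None
        e, c, h, p, i = tup
        return SubscaleScores(
            emotional=e, conduct=c, hyperactivity=h, peer=p, impact=i
        )

    fields = dict(
        id=id,
        school_id="SCH001",
        t1=scores(t1),
        t2=scores(t2),
        gender="female",
        ethnicity="White",
        fsm=False,
        sen=False,
        attainment=28.0,
        school_climate=9,
        quality_of_life=25,
        duration="none",
        support_counsellor=False,
        support_peer_mentor=False,
        support_other=False,
    )
    fields.update(overrides)
    return StudentRecord(**fields)


@pytest.fixture(scope="session")
def cohort300():
    return generate(CohortConfig(n=300, seed=123))


@pytest.fixture(scope="session")
def classified300(cohort300):
    from sdqchange import classify_cohort

    return cohort300, classify_cohort(cohort300)


@pytest.fixture(scope="session")
def cohort_no_attrition():
    return CohortConfig(n=300, seed=123, attrition=AttritionConfig(enabled=False))
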