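import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from cdexposure import (
    AdministrationRecord,
    CohortConfig,
    StayRecord,
    build_daily_exposure,
    figure1_fixture,
    generate_cohort,
    toy_knowledge_tables,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_tables():
    return toy_knowledge_tables()


@pytest.fixture(scope="session")
def fig1_daily():
    """Daily exposure matrix of the deterministic worked-example patient."""
    fix = figure1_fixture()
    return build_daily_exposure(fix.administrations, fix.stays[0])


@pytest.fixture(scope="session")
def cohort200():
    """200-patient synthetic cohort at default generator settings."""
    return generate_cohort(CohortConfig(n_patients=200, seed=2024))


def make_four_ddi_patient(kb):
    """One patient with exactly four distinct interactions on a single day.

    On day 2 of a 3-day stay the administered set fires four knowledge-table
    pairs (two major, two moderate); days 1 and 3 carry one inert drug.
    """
    pid = "X0001"
    adm = dt.date(2021, 6, 1)
    stay = StayRecord(
        patient_id=pid,
        admission_date=adm,
        discharge_date=adm + dt.timedelta(days=2),
        age_years=50,
    )
    day2 = [
        "C01CA03", "C07AB02",  # contraindicated pair
        "N06AB03", "N02AA01",  # should-be-avoided pair
        "A02BC05", "C03CA01",  # precaution-of-use pair (level-4 terms)
        "B01AC06", "B01AB01",  # precaution-of-use pair
    ]
    records = [AdministrationRecord(pid, adm, "N02BE01"), AdministrationRecord(pid, adm + dt.timedelta(days=2), "N02BE01")]
    records += [AdministrationRecord(pid, adm + dt.timedelta(days=1), c) for c in day2]
    return records, stay


@pytest.fixture(scope="session")
def four_ddi_patient(toy_tables):
    kb, _ = toy_tables
    return make_four_ddi_patient(kb)
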