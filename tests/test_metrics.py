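import datetime as dt

import pytest

from cdexposure import (
    AdministrationRecord,
    StayRecord,
    build_daily_exposure,
    classify_trajectory,
    cohort_summary,
    compute_cde,
    compute_cded,
    conventional_metrics,
    patient_metrics,
)
from cdexposure.metrics import (
    DDI,
    DDI_MAJOR,
    DDI_MODERATE,
    DETERMINANTS,
    HPP,
    PIM,
    PP,
    metrics_frame,
)
from cdexposure.records_io import ValidationError


def _cohort_dailies(cohort, toy_tables, n=40):
    kb, pims = toy_tables
    dailies = {}
    for stay in cohort.stays[:n]:
        recs = [r for r in cohort.administrations if r.patient_id == stay.patient_id]
        dailies[stay.patient_id] = build_daily_exposure(recs, stay, kb=kb, pim_list=pims)
    return dailies


class TestComputeCDE:
    def test_worked_example_pp_and_hpp(self, fig1_daily):
        assert compute_cde(fig1_daily, PP) == 24
        assert compute_cde(fig1_daily, HPP) == 7

    def test_four_same_day_ddis_count_four_occurrence_days(self, four_ddi_patient, toy_tables):
        kb, _ = toy_tables
        records, stay = four_ddi_patient
        daily = build_daily_exposure(records, stay, kb=kb)
        assert [len(d.ddi_events) for d in daily] == [0, 4, 0]
        assert compute_cde(daily, DDI) == 4
        assert compute_cde(daily, DDI_MAJOR) == 2
        assert compute_cde(daily, DDI_MODERATE) == 2

    def test_no_exposure_gives_zero_and_pim_na_gives_none(self, fig1_daily):
        assert compute_cde(fig1_daily, DDI) >= 0
        # fixture patient is 60: PIM not applicable, never zero
        assert compute_cde(fig1_daily, PIM) is None

    def test_empty_daily_rejected(self):
        with pytest.raises(ValidationError):
            compute_cde([], PP)


class TestComputeCDED:
    @pytest.mark.parametrize("cde,los,expected", [(0, 19, 0.0), (24, 34, 24 / 34), (17, 17, 1.0)])
    def test_direct_ratio(self, cde, los, expected):
        assert compute_cded(cde, los) == pytest.approx(expected)

    def test_invalid_los_rejected(self):
        with pytest.raises(ValidationError):
            compute_cded(5, 0)


class TestConventionalMetrics:
    def test_worked_example_admission_present_discharge_absent(self, fig1_daily):
        adm, dis, c_adm, c_dis, any_day = conventional_metrics(fig1_daily, PP)
        assert (adm, dis) == (True, False)
        assert (c_adm, c_dis) == (5, 1)
        assert any_day

    def test_single_day_stay_uses_same_day_twice(self):
        stay = StayRecord("p1", dt.date(2021, 1, 1), dt.date(2021, 1, 1), age_years=40)
        recs = [
            AdministrationRecord("p1", dt.date(2021, 1, 1), c)
            for c in ("N02BE01", "A02BC01", "J01CR05", "C07AB02", "B01AC06")
        ]
        daily = build_daily_exposure(recs, stay)
        adm, dis, c_adm, c_dis, _ = conventional_metrics(daily, PP)
        assert adm is dis is True and c_adm == c_dis == 5

    def test_all_zero_days(self):
        stay = StayRecord("p1", dt.date(2021, 1, 1), dt.date(2021, 1, 3), age_years=40)
        daily = build_daily_exposure([], stay)
        assert conventional_metrics(daily, PP) == (False, False, 0, 0, False)


@pytest.mark.parametrize(
    "adm,dis,label",
    [(False, False, "0→0"), (False, True, "0→1"), (True, False, "1→0"), (True, True, "1→1")],
)
def test_classify_trajectory(adm, dis, label):
    assert classify_trajectory(adm, dis) == label


class TestStructuralInvariants:
    def test_cded_bounds_severity_partition_and_consistency(self, cohort200, toy_tables):
        dailies = _cohort_dailies(cohort200, toy_tables)
        for pid, daily in dailies.items():
            ms = {m.determinant: m for m in patient_metrics(daily)}
            assert 0.0 <= ms[PP].cded <= 1.0
            assert 0.0 <= ms[HPP].cded <= 1.0
            assert ms[HPP].cde <= ms[PP].cde
            assert ms[DDI].cde == ms[DDI_MAJOR].cde + ms[DDI_MODERATE].cde
            for m in ms.values():
                if m.applicable:
                    assert m.cded == pytest.approx(m.cde / m.los_days)
                    assert m.present_any_day == (m.cde > 0)
            # conventional counts equal the day-1 / last-day daily values
            assert ms[PP].count_admission == daily[0].n_distinct_drugs
            assert ms[PP].count_discharge == daily[-1].n_distinct_drugs
            assert ms[DDI].count_admission == len(daily[0].ddi_events)
            assert ms[DDI].count_discharge == len(daily[-1].ddi_events)

    def test_metrics_deterministic_under_record_permutation(self, cohort200, toy_tables):
        kb, pims = toy_tables
        stay = cohort200.stays[5]
        recs = [r for r in cohort200.administrations if r.patient_id == stay.patient_id]
        a = patient_metrics(build_daily_exposure(recs, stay, kb=kb, pim_list=pims))
        b = patient_metrics(build_daily_exposure(recs[::-1], stay, kb=kb, pim_list=pims))
        assert a == b

    def test_pim_not_applicable_propagates_as_missing(self, cohort200, toy_tables):
        dailies = _cohort_dailies(cohort200, toy_tables)
        ages = {s.patient_id: s.age_years for s in cohort200.stays}
        for pid, daily in dailies.items():
            (pim,) = [m for m in patient_metrics(daily) if m.determinant == PIM]
            if ages[pid] < 65:
                assert not pim.applicable and pim.cde is None and pim.cded is None
            else:
                assert pim.applicable and pim.cde is not None


class TestCohortSummary:
    def test_two_patient_prevalence(self):
        adm = dt.date(2021, 1, 1)
        dailies = {}
        for pid, n_codes in (("a", 6), ("b", 2)):
            stay = StayRecord(pid, adm, adm + dt.timedelta(days=1), age_years=50)
            codes = ["N02BE01", "A02BC01", "J01CR05", "C07AB02", "B01AC06", "N05BA01"][:n_codes]
            recs = [AdministrationRecord(pid, adm, c) for c in codes]
            dailies[pid] = build_daily_exposure(recs, stay)
        metrics = [m for d in dailies.values() for m in patient_metrics(d, [PP, HPP])]
        summary = cohort_summary(metrics, dailies)
        prev = summary["determinants"][PP]["prevalence"]["stay"]
        assert (prev["numerator"], prev["denominator"], prev["pct"]) == (1, 2, 50.0)

    def test_saturated_cohort(self):
        adm = dt.date(2021, 1, 1)
        codes = ["N02BE01", "A02BC01", "J01CR05", "C07AB02", "B01AC06"]
        dailies = {}
        for pid in ("a", "b", "c"):
            stay = StayRecord(pid, adm, adm + dt.timedelta(days=3), age_years=50)
            recs = [
                AdministrationRecord(pid, adm + dt.timedelta(days=d), c)
                for d in range(4)
                for c in codes
            ]
            dailies[pid] = build_daily_exposure(recs, stay)
        metrics = [m for d in dailies.values() for m in patient_metrics(d, [PP])]
        summary = cohort_summary(metrics, dailies)
        det = summary["determinants"][PP]
        assert det["prevalence"]["stay"]["pct"] == 100.0
        assert det["mean_cded"] == pytest.approx(1.0)
        assert det["mean_count_per_day"]["stay"] == pytest.approx(5.0)

    def test_prevalences_match_brute_force_recount(self, cohort200, toy_tables):
        dailies = _cohort_dailies(cohort200, toy_tables, n=60)
        metrics = [m for d in dailies.values() for m in patient_metrics(d)]
        summary = cohort_summary(metrics, dailies)
        # independent recount straight from the daily matrices
        for det, flag in ((PP, "pp"), (HPP, "hpp")):
            expected = sum(any(getattr(d, flag) for d in daily) for daily in dailies.values())
            assert summary["determinants"][det]["prevalence"]["stay"]["numerator"] == expected
        n_ddi = sum(any(d.ddi_events for d in daily) for daily in dailies.values())
        assert summary["determinants"][DDI]["prevalence"]["stay"]["numerator"] == n_ddi
        aged = [daily for daily in dailies.values() if daily[0].pim_codes is not None]
        pim_summary = summary["determinants"][PIM]
        assert pim_summary["prevalence"]["stay"]["denominator"] == len(aged)
        assert pim_summary["prevalence"]["stay"]["numerator"] == sum(
            any(d.pim_codes for d in daily) for daily in aged
        )

    def test_metrics_frame_has_contracted_columns(self, fig1_daily):
        frame = metrics_frame(patient_metrics(fig1_daily, DETERMINANTS))
        assert list(frame.columns) == [
            "patient_id", "determinant", "cde", "cded", "los_days",
            "present_admission", "present_discharge", "count_admission",
            "count_discharge", "present_any_day", "trajectory", "applicable",
        ]
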