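"""Cumulative and conventional drug-exposure metrics.

Two cumulative metrics summarize each determinant over the whole stay:

* **CDE** (cumulative drug exposure) — for PP and HPP, the number of days the
  determinant was present; for DDIs and PIMs, occurrence-days: every distinct
  same-day event contributes separately, so four distinct interactions on one
  day add four.
* **CDED** (cumulative drug exposure density) — CDE divided by the length of
  stay, an intensity-adjusted measure.  For PP/HPP it lies in [0, 1]; for
  DDIs/PIMs it is the mean number of daily events and may exceed 1.

Conventional point-in-time metrics (presence and count at admission — first
day — and discharge — last day) and the four admission→discharge trajectory
groups (0→0, 0→1, 1→0, 1→1) are computed alongside for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .determinants import DailyExposure
from .records_io import MAJOR, MODERATE, ValidationError

logger = logging.getLogger("cdexposure")

__all__ = [
    "PP",
    "HPP",
    "DDI",
    "DDI_MAJOR",
    "DDI_MODERATE",
    "PIM",
    "DETERMINANTS",
    "DeterminantMetrics",
    "compute_cde",
    "compute_cded",
    "conventional_metrics",
    "classify_trajectory",
    "patient_metrics",
    "metrics_frame",
    "daily_exposure_frame",
    "cohort_summary",
]

PP = "PP"
HPP = "HPP"
DDI = "DDI"
DDI_MAJOR = "DDI_major"
DDI_MODERATE = "DDI_moderate"
PIM = "PIM"

#: All determinants, in reporting order.  The severity-restricted DDI
#: variants are first-class so severity sub-rows of cohort tables can be
#: reproduced structurally.
DETERMINANTS = (PP, HPP, DDI, DDI_MAJOR, DDI_MODERATE, PIM)

TRAJECTORIES = ("0→0", "0→1", "1→0", "1→1")


@dataclass(frozen=True)
class DeterminantMetrics:
    """All exposure metrics of one patient for one determinant.

    ``applicable`` is False (and every metric ``None``) when the determinant
    does not apply to the patient — PIMs in patients under the age threshold.
    """

    patient_id: str
    determinant: str
    applicable: bool
    los_days: int
    cde: int | None
    cded: float | None
    present_admission: bool | None
    present_discharge: bool | None
    count_admission: int | None
    count_discharge: int | None
    present_any_day: bool | None
    trajectory: str | None


def _day_events(day: DailyExposure, determinant: str) -> int | None:
    """Event count of one determinant on one day; None when not applicable."""
    if determinant == PP:
        return int(day.pp)
    if determinant == HPP:
        return int(day.hpp)
    if determinant == DDI:
        return len(day.ddi_events)
    if determinant == DDI_MAJOR:
        return sum(1 for e in day.ddi_events if e.severity_group == MAJOR)
    if determinant == DDI_MODERATE:
        return sum(1 for e in day.ddi_events if e.severity_group == MODERATE)
    if determinant == PIM:
        return None if day.pim_codes is None else len(day.pim_codes)
    raise ValidationError(f"Unknown determinant {determinant!r}")


def _day_count(day: DailyExposure, determinant: str) -> int | None:
    """Conventional count of one determinant on one day (drugs for PP/HPP,
    events for DDIs, listed medications for PIMs)."""
    if determinant in (PP, HPP):
        return day.n_distinct_drugs
    return _day_events(day, determinant)


def compute_cde(daily: Sequence[DailyExposure], determinant: str) -> int | None:
    """Cumulative drug exposure over the stay.

    Days with the flag set for PP/HPP; occurrence-days (sum of distinct daily
    events) for DDIs and PIMs.  Returns ``None`` when the determinant is not
    applicable to this patient, never zero in that case.
    """
    if not daily:
        raise ValidationError("compute_cde needs a non-empty daily matrix")
    total = 0
    for day in daily:
        events = _day_events(day, determinant)
        if events is None:
            return None
        total += events
    return total


def compute_cded(cde: int | float | None, los_days: int) -> float | None:
    """Exposure density: CDE normalized by the length of stay."""
    if los_days < 1:
        raise ValidationError(f"Length of stay must be >= 1 day, got {los_days}")
    if cde is None:
        return None
    return cde / los_days


def classify_trajectory(present_admission: bool, present_discharge: bool) -> str:
    """Admission→discharge trajectory label (0 = absent, 1 = present)."""
    return f"{int(present_admission)}→{int(present_discharge)}"


def conventional_metrics(
    daily: Sequence[DailyExposure], determinant: str
) -> tuple[bool, bool, int, int, bool] | None:
    """Point-in-time metrics: presence and counts at admission (first day)
    and discharge (last day), plus presence on any day of the stay.

    Returns ``None`` when the determinant is not applicable.  On a
    single-day stay admission and discharge are the same day.
    """
    if not daily:
        raise ValidationError("conventional_metrics needs a non-empty daily matrix")
    first, last = daily[0], daily[-1]
    counts = [_day_events(d, determinant) for d in daily]
    if any(c is None for c in counts):
        return None
    present_admission = counts[0] > 0
    present_discharge = counts[-1] > 0
    present_any_day = any(c > 0 for c in counts)
    return (
        present_admission,
        present_discharge,
        _day_count(first, determinant),
        _day_count(last, determinant),
        present_any_day,
    )


def patient_metrics(
    daily: Sequence[DailyExposure],
    determinants: Sequence[str] = DETERMINANTS,
) -> list[DeterminantMetrics]:
    """Full metric set of one patient for the requested determinants."""
    if not daily:
        raise ValidationError("patient_metrics needs a non-empty daily matrix")
    patient_id = daily[0].patient_id
    los = len(daily)
    out: list[DeterminantMetrics] = []
    for det in determinants:
        cde = compute_cde(daily, det)
        if cde is None:
            out.append(
                DeterminantMetrics(
                    patient_id=patient_id,
                    determinant=det,
                    applicable=False,
                    los_days=los,
                    cde=None,
                    cded=None,
                    present_admission=None,
                    present_discharge=None,
                    count_admission=None,
                    count_discharge=None,
                    present_any_day=None,
                    trajectory=None,
                )
            )
            continue
        adm, dis, c_adm, c_dis, any_day = conventional_metrics(daily, det)
        out.append(
            DeterminantMetrics(
                patient_id=patient_id,
                determinant=det,
                applicable=True,
                los_days=los,
                cde=cde,
                cded=compute_cded(cde, los),
                present_admission=adm,
                present_discharge=dis,
                count_admission=c_adm,
                count_discharge=c_dis,
                present_any_day=any_day,
                trajectory=classify_trajectory(adm, dis),
            )
        )
    return out


# --------------------------------------------------------------------------
# Tabular views
# --------------------------------------------------------------------------


def metrics_frame(metrics: Iterable[DeterminantMetrics]) -> pd.DataFrame:
    """Long-format metrics table, one row per patient × determinant."""
    rows = [
        {
            "patient_id": m.patient_id,
            "determinant": m.determinant,
            "cde": m.cde,
            "cded": m.cded,
            "los_days": m.los_days,
            "present_admission": m.present_admission,
            "present_discharge": m.present_discharge,
            "count_admission": m.count_admission,
            "count_discharge": m.count_discharge,
            "present_any_day": m.present_any_day,
            "trajectory": m.trajectory,
            "applicable": m.applicable,
        }
        for m in metrics
    ]
    frame = pd.DataFrame(rows)
    for col in ("cde", "count_admission", "count_discharge"):
        frame[col] = frame[col].astype("Int64")
    return frame


def daily_exposure_frame(dailies: Iterable[Sequence[DailyExposure]]) -> pd.DataFrame:
    """Long-format daily matrix, one row per patient-day."""
    rows = []
    for daily in dailies:
        for d in daily:
            rows.append(
                {
                    "patient_id": d.patient_id,
                    "day_index": d.day_index,
                    "date": d.date.isoformat(),
                    "n_distinct_drugs": d.n_distinct_drugs,
                    "pp": d.pp,
                    "hpp": d.hpp,
                    "n_ddis": len(d.ddi_events),
                    "n_ddis_major": sum(
                        1 for e in d.ddi_events if e.severity_group == MAJOR
                    ),
                    "n_ddis_moderate": sum(
                        1 for e in d.ddi_events if e.severity_group == MODERATE
                    ),
                    "n_pims": None if d.pim_codes is None else len(d.pim_codes),
                }
            )
    frame = pd.DataFrame(rows)
    frame["n_pims"] = frame["n_pims"].astype("Int64")
    return frame


# --------------------------------------------------------------------------
# Cohort summary
# --------------------------------------------------------------------------


def cohort_summary(
    metrics: Sequence[DeterminantMetrics],
    dailies: Mapping[str, Sequence[DailyExposure]],
) -> dict:
    """Cohort-level summary per determinant.

    Stay-level prevalence counts a patient once if the determinant was
    present on at least one day.  The mean count per day over the stay is
    pooled over all applicable patient-days (sum of daily counts divided by
    the summed length of stay); admission/discharge means average over
    patients.  PIM rows use the applicable (aged) subgroup as denominator.
    """
    if not metrics:
        raise ValidationError("cohort_summary needs at least one patient metric")
    summary: dict = {"n_patients": len({m.patient_id for m in metrics}), "determinants": {}}
    by_det: dict[str, list[DeterminantMetrics]] = {}
    for m in metrics:
        by_det.setdefault(m.determinant, []).append(m)
    for det, ms in by_det.items():
        applicable = [m for m in ms if m.applicable]
        n_app = len(applicable)
        entry: dict = {
            "n_applicable": n_app,
            "n_total": len(ms),
        }
        if n_app == 0:
            entry["not_applicable"] = True
            summary["determinants"][det] = entry
            continue

        def prevalence(flags: list[bool]) -> dict:
            num = sum(flags)
            return {"numerator": num, "denominator": n_app, "pct": 100.0 * num / n_app}

        entry["prevalence"] = {
            "stay": prevalence([m.present_any_day for m in applicable]),
            "admission": prevalence([m.present_admission for m in applicable]),
            "discharge": prevalence([m.present_discharge for m in applicable]),
        }
        total_days = sum(m.los_days for m in applicable)
        pooled = sum(
            c
            for m in applicable
            for c in (
                _day_count(d, det) for d in dailies[m.patient_id]
            )
        )
        entry["mean_count_per_day"] = {
            "stay": pooled / total_days,
            "admission": sum(m.count_admission for m in applicable) / n_app,
            "discharge": sum(m.count_discharge for m in applicable) / n_app,
        }
        entry["mean_cde"] = sum(m.cde for m in applicable) / n_app
        entry["mean_cded"] = sum(m.cded for m in applicable) / n_app
        summary["determinants"][det] = entry
    return summary
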