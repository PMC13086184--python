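"""Daily detection of prescribing determinants.

For every calendar day of a patient's stay this module computes the number of
distinct drugs administered and derives four determinants:

* **polypharmacy (PP)** — at least ``pp_threshold`` (default 5) distinct drugs
  on the day;
* **hyperpolypharmacy (HPP)** — at least ``hpp_threshold`` (default 10);
* **drug-drug interactions (DDIs)** — both members of a knowledge-table pair
  administered on the same day; severities collapse to major/moderate;
* **potentially inappropriate medications (PIMs)** — administered codes
  matching a reference list, assessed only for patients aged
  ``pim_age_min`` (default 65) or older.

During the pre-transplant conditioning phase, antineoplastic agents (ATC
class L01) are excluded from the distinct-drug count so that high-dose
chemotherapy protocols do not inflate the polypharmacy signal.  The exclusion
applies only to the PP/HPP count: DDI and PIM screening always sees the full
day's administrations.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records_io import (
    MAJOR,
    MODERATE,
    AdministrationRecord,
    DDIKnowledgeTable,
    PIMList,
    StayRecord,
    ValidationError,
)

logger = logging.getLogger("cdexposure")

__all__ = [
    "Thresholds",
    "DDIEvent",
    "DailyExposure",
    "ATC_LEVEL_LENGTHS",
    "atc_matches",
    "roll_up_code",
    "count_distinct_drugs",
    "detect_ddis",
    "detect_pims",
    "build_daily_exposure",
]

#: Character length of an ATC term at each hierarchy level.
ATC_LEVEL_LENGTHS: Mapping[int, int] = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


@dataclass(frozen=True)
class Thresholds:
    """Determinant thresholds: PP >= pp_threshold distinct drugs per day,
    HPP >= hpp_threshold, PIM screening from pim_age_min years of age."""

    pp_threshold: int = 5
    hpp_threshold: int = 10
    pim_age_min: int = 65

    def __post_init__(self) -> None:
        if not (1 <= self.pp_threshold <= self.hpp_threshold):
            raise ValidationError(
                f"Thresholds must satisfy 1 <= pp ({self.pp_threshold}) <= "
                f"hpp ({self.hpp_threshold})"
            )


@dataclass(frozen=True, order=True)
class DDIEvent:
    """A fired interaction: canonically sorted unordered term pair."""

    term1: str
    term2: str
    severity_group: str = MODERATE


@dataclass(frozen=True)
class DailyExposure:
    """Exposure state of one patient on one hospitalization day.

    ``day_index`` is 1-based (1 = admission day).  ``pim_codes`` is ``None``
    when the PIM determinant is not applicable (patient under the age
    threshold, or no PIM list supplied) — deliberately distinct from an empty
    set, so cohort summaries can use the correct subgroup denominator.
    """

    patient_id: str
    day_index: int
    date: _dt.date
    n_distinct_drugs: int
    pp: bool
    hpp: bool
    ddi_events: frozenset[DDIEvent] = frozenset()
    pim_codes: frozenset[str] | None = None
    atc_set_raw: frozenset[str] = frozenset()


def atc_matches(code: str, term: str) -> bool:
    """True iff ``code`` descends from (or equals) the ATC ``term``.

    Prefix semantics: a term at any level matches itself and every
    descendant, e.g. ``L01`` matches ``L01XX05``.
    """
    return code.startswith(term)


def roll_up_code(code: str, level: int) -> str:
    """Truncate an ATC code to the given hierarchy level (1-5).

    Codes already coarser than the requested level are returned unchanged.
    """
    if level not in ATC_LEVEL_LENGTHS:
        raise ValidationError(f"ATC level must be 1-5, got {level}")
    return code[: ATC_LEVEL_LENGTHS[level]]


def count_distinct_drugs(
    day_codes: Iterable[str],
    is_pre_transplant: bool = False,
    count_level: int | None = None,
) -> int:
    """Number of distinct drugs administered on one day.

    Repeated administrations of the same code count once.  On pre-transplant
    days, ATC class L01 (antineoplastics) is excluded.  ``count_level`` rolls
    codes up to a coarser ATC level before counting; by default codes are
    counted as given (typically level-5 substances).
    """
    codes = set(day_codes)
    if is_pre_transplant:
        codes = {c for c in codes if not atc_matches(c, "L01")}
    if count_level is not None:
        codes = {roll_up_code(c, count_level) for c in codes}
    return len(codes)


def detect_ddis(day_codes: Iterable[str], kb: DDIKnowledgeTable) -> frozenset[DDIEvent]:
    """Interactions fired by one day's administrations.

    An entry fires when two *distinct* codes match its two terms (a single
    drug cannot interact with itself, even when it matches both terms).
    Events are deduplicated by canonical (sorted) term pair; if several
    knowledge rows yield the same pair, the worst severity (major) wins.
    """
    codes = list(set(day_codes))
    fired: dict[tuple[str, str], str] = {}
    for entry in kb.entries:
        hit = any(
            a != b and atc_matches(a, entry.term1) and atc_matches(b, entry.term2)
            for a in codes
            for b in codes
        )
        if not hit:
            continue
        pair = tuple(sorted((entry.term1, entry.term2)))
        if pair not in fired or entry.severity_group == MAJOR:
            fired[pair] = entry.severity_group
    return frozenset(
        DDIEvent(term1=p[0], term2=p[1], severity_group=g) for p, g in fired.items()
    )


def detect_pims(
    day_codes: Iterable[str],
    pim_list: PIMList,
    age_years: int,
    thresholds: Thresholds = Thresholds(),
) -> frozenset[str] | None:
    """PIM terms matched by one day's administrations.

    Returns ``None`` (not applicable, distinct from the empty set) for
    patients under the age threshold; otherwise the set of listed terms
    matched by at least one administered code.
    """
    if age_years < thresholds.pim_age_min:
        return None
    codes = set(day_codes)
    return frozenset(
        term for term in pim_list.terms if any(atc_matches(c, term) for c in codes)
    )


def build_daily_exposure(
    records: Sequence[AdministrationRecord],
    stay: StayRecord,
    kb: DDIKnowledgeTable | None = None,
    pim_list: PIMList | None = None,
    thresholds: Thresholds = Thresholds(),
    count_level: int | None = None,
) -> list[DailyExposure]:
    """Daily exposure matrix for one patient: one entry per calendar day.

    Exactly ``(discharge - admission) + 1`` entries are produced; days
    without administrations carry a zero count and empty event sets.  A day
    is pre-transplant when its date is strictly earlier than the transplant
    date (the transplant day itself is not excluded); without a transplant
    date the L01 exclusion is inert.
    """
    if stay is None:
        raise ValidationError("build_daily_exposure requires a stay record")
    by_date: dict[_dt.date, set[str]] = defaultdict(set)
    for rec in records:
        if rec.patient_id != stay.patient_id:
            raise ValidationError(
                f"Record for patient {rec.patient_id!r} passed with stay of "
                f"{stay.patient_id!r}"
            )
        by_date[rec.date].add(rec.atc_code)

    days: list[DailyExposure] = []
    for offset in range(stay.los_days):
        date = stay.admission_date + _dt.timedelta(days=offset)
        codes = frozenset(by_date.get(date, set()))
        pre_tx = stay.transplant_date is not None and date < stay.transplant_date
        n = count_distinct_drugs(codes, is_pre_transplant=pre_tx, count_level=count_level)
        days.append(
            DailyExposure(
                patient_id=stay.patient_id,
                day_index=offset + 1,
                date=date,
                n_distinct_drugs=n,
                pp=n >= thresholds.pp_threshold,
                hpp=n >= thresholds.hpp_threshold,
                ddi_events=detect_ddis(codes, kb) if kb is not None else frozenset(),
                pim_codes=(
                    detect_pims(codes, pim_list, stay.age_years, thresholds)
                    if pim_list is not None
                    else None
                ),
                atc_set_raw=codes,
            )
        )
    return days
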