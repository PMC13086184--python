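"""Reading, validation and normalization of the pipeline's input tables.

Four plain-CSV/text formats are understood, all UTF-8, comma-separated,
header row required, ISO-8601 dates:

* ``administrations.csv`` — ``patient_id,date,atc_code[,drug_label]``;
  one row per drug-administration event.
* ``stays.csv`` — ``patient_id,admission_date,discharge_date[,transplant_date],age_years``;
  one row per patient (the index stay).
* ``ddi_table.csv`` — ``term1,term2,level``; interacting ATC term pairs with a
  four-level severity that is mapped onto the two analysis groups
  ``major`` / ``moderate``.
* ``pim_list.txt`` — one ATC term per line, ``#`` comments allowed.

ATC terms may sit at any level of the WHO hierarchy (1, 3, 4, 5 or 7
characters); administration records are typically level-5 substance codes but
coarser codes are accepted and treated as distinct drug entities.
Timestamps on administration dates are truncated to the calendar day, which is
the unit of analysis throughout.
"""

from __future__ import annotations

import datetime as _dt
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

logger = logging.getLogger("cdexposure")

Source = Union[str, Path, io.IOBase]

__all__ = [
    "ValidationError",
    "AdministrationRecord",
    "StayRecord",
    "DDIEntry",
    "DDIKnowledgeTable",
    "PIMList",
    "validate_atc",
    "read_administrations",
    "read_stays",
    "read_ddi_table",
    "read_pim_list",
    "filter_records_to_stays",
    "write_administrations",
    "write_stays",
    "write_ddi_table",
    "write_pim_list",
    "write_table",
    "SEVERITY_GROUP",
    "MAJOR",
    "MODERATE",
]


class ValidationError(ValueError):
    """Raised when an input value or table violates the format contracts."""


# --------------------------------------------------------------------------
# ATC code validation
# --------------------------------------------------------------------------

# Level boundaries of the WHO ATC hierarchy: anatomical main group (1 char),
# therapeutic subgroup (3), pharmacological subgroup (4), chemical subgroup
# (5), chemical substance (7).
_ATC_LENGTHS = frozenset({1, 3, 4, 5, 7})
_ATC_RE = re.compile(r"^[A-Z](?:[0-9]{2}(?:[A-Z](?:[A-Z](?:[0-9]{2})?)?)?)?$")


def validate_atc(code: str) -> str:
    """Normalize and validate an ATC term at any hierarchy level.

    Upper-cases and strips whitespace, then checks that the result is a
    prefix of the ATC grammar ``letter / 2 digits / letter / letter /
    2 digits`` truncated at a level boundary (lengths 1, 3, 4, 5 or 7).

    Raises :class:`ValidationError` naming the offending code otherwise.
    Idempotent on valid input.
    """
    if not isinstance(code, str) or not code.strip():
        raise ValidationError(f"ATC code must be a non-empty string, got {code!r}")
    norm = code.strip().upper()
    if len(norm) not in _ATC_LENGTHS or not _ATC_RE.match(norm):
        raise ValidationError(
            f"Malformed ATC code {code!r}: expected letter/2 digits/letter/"
            f"letter/2 digits truncated at a level boundary (1, 3, 4, 5 or 7 "
            f"characters)"
        )
    return norm


# --------------------------------------------------------------------------
# Domain records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AdministrationRecord:
    """One drug-administration event: patient, calendar date, ATC code."""

    patient_id: str
    date: _dt.date
    atc_code: str
    drug_label: str | None = None


@dataclass(frozen=True)
class StayRecord:
    """Index hospital stay of one patient.

    ``age_years`` is the age at admission and is held constant across the
    stay.  ``transplant_date``, when present, marks the day of the graft;
    days strictly before it are the conditioning phase during which
    antineoplastic (L01) administrations are excluded from the daily
    distinct-drug count.
    """

    patient_id: str
    admission_date: _dt.date
    discharge_date: _dt.date
    age_years: int
    transplant_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.admission_date > self.discharge_date:
            raise ValidationError(
                f"Stay of patient {self.patient_id!r}: admission "
                f"{self.admission_date} after discharge {self.discharge_date}"
            )
        if self.transplant_date is not None and not (
            self.admission_date <= self.transplant_date <= self.discharge_date
        ):
            raise ValidationError(
                f"Stay of patient {self.patient_id!r}: transplant date "
                f"{self.transplant_date} outside [admission, discharge]"
            )
        if self.age_years < 0:
            raise ValidationError(
                f"Stay of patient {self.patient_id!r}: negative age"
            )

    @property
    def los_days(self) -> int:
        """Length of stay in days, both boundary days counted."""
        return (self.discharge_date - self.admission_date).days + 1


MAJOR = "major"
MODERATE = "moderate"

#: Mapping from accepted severity strings (the four knowledge-base levels plus
#: the two analysis groups; "minor" is an accepted synonym of "moderate") onto
#: the two severity groups used downstream.
SEVERITY_GROUP: dict[str, str] = {
    "contraindicated": MAJOR,
    "should_be_avoided": MAJOR,
    "precaution_of_use": MODERATE,
    "to_take_into_account": MODERATE,
    "major": MAJOR,
    "moderate": MODERATE,
    "minor": MODERATE,
}


def _normalize_severity(level: str) -> str:
    key = re.sub(r"[\s\-]+", "_", str(level).strip().lower())
    try:
        return SEVERITY_GROUP[key]
    except KeyError:
        raise ValidationError(
            f"Unknown DDI severity {level!r}; allowed values: "
            + ", ".join(sorted(set(SEVERITY_GROUP)))
        ) from None


@dataclass(frozen=True)
class DDIEntry:
    """An interacting ATC term pair with its severity group."""

    term1: str
    term2: str
    level: str
    severity_group: str


@dataclass
class DDIKnowledgeTable:
    """Knowledge base of interacting ATC term pairs.

    Terms may sit at any ATC level; a term matches itself and all of its
    descendants (prefix semantics).  The four knowledge-base severity levels
    collapse onto two analysis groups: ``major`` (contraindicated, should be
    avoided) and ``moderate`` (precaution of use, to take into account).
    """

    entries: list[DDIEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PIMList:
    """Set of ATC terms flagging potentially inappropriate medications.

    Terms are prefixes: any administered code descending from a listed term
    counts as that PIM.
    """

    terms: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.terms)


# --------------------------------------------------------------------------
# Parsing helpers
# --------------------------------------------------------------------------


def _parse_date(raw: str, where: str) -> _dt.date:
    """Parse an ISO-8601 date or datetime, truncating to the calendar day."""
    text = str(raw).strip()
    try:
        return _dt.date.fromisoformat(text)
    except ValueError:
        pass
    try:
        return _dt.datetime.fromisoformat(text).date()
    except ValueError:
        raise ValidationError(f"{where}: unparseable ISO-8601 date {raw!r}") from None


def _read_csv(source: Source, required: Sequence[str], what: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False, skipinitialspace=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{what}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what}: missing required column(s) {missing}")
    return frame


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------


def read_administrations(source: Source) -> list[AdministrationRecord]:
    """Read a drug-administration table.

    Every row is validated (row numbers are 1-based data rows, header
    excluded).  Duplicate rows are preserved: per-day deduplication belongs to
    the daily-exposure builder, not the reader.
    """
    frame = _read_csv(source, ["patient_id", "date", "atc_code"], "administrations")
    has_label = "drug_label" in frame.columns
    records: list[AdministrationRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        where = f"administrations row {i}"
        pid = str(row.patient_id).strip()
        if not pid:
            raise ValidationError(f"{where}: empty patient_id")
        try:
            code = validate_atc(row.atc_code)
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from None
        label = (str(row.drug_label).strip() or None) if has_label else None
        records.append(
            AdministrationRecord(
                patient_id=pid,
                date=_parse_date(row.date, where),
                atc_code=code,
                drug_label=label,
            )
        )
    return records


def read_stays(source: Source) -> list[StayRecord]:
    """Read the stay-metadata table; one row per patient (the index stay)."""
    frame = _read_csv(
        source, ["patient_id", "admission_date", "discharge_date", "age_years"], "stays"
    )
    has_tx = "transplant_date" in frame.columns
    stays: list[StayRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        where = f"stays row {i}"
        pid = str(row.patient_id).strip()
        if not pid:
            raise ValidationError(f"{where}: empty patient_id")
        if pid in seen:
            raise ValidationError(
                f"{where}: duplicate patient_id {pid!r} (one index stay per patient)"
            )
        seen.add(pid)
        tx_raw = str(row.transplant_date).strip() if has_tx else ""
        try:
            age = int(str(row.age_years).strip())
        except ValueError:
            raise ValidationError(f"{where}: age_years {row.age_years!r} is not an integer") from None
        stays.append(
            StayRecord(
                patient_id=pid,
                admission_date=_parse_date(row.admission_date, where),
                discharge_date=_parse_date(row.discharge_date, where),
                transplant_date=_parse_date(tx_raw, where) if tx_raw else None,
                age_years=age,
            )
        )
    return stays


def read_ddi_table(source: Source) -> DDIKnowledgeTable:
    """Read the interacting-pair knowledge table.

    Severity strings are matched case-insensitively against the four
    knowledge-base levels (spaces and hyphens tolerated); the group labels
    ``major``/``moderate``/``minor`` are accepted as well.
    """
    frame = _read_csv(source, ["term1", "term2", "level"], "ddi_table")
    entries: list[DDIEntry] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        where = f"ddi_table row {i}"
        try:
            t1 = validate_atc(row.term1)
            t2 = validate_atc(row.term2)
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from None
        if t1 == t2:
            raise ValidationError(f"{where}: term1 equals term2 ({t1!r}) after normalization")
        group = _normalize_severity(row.level)
        entries.append(
            DDIEntry(term1=t1, term2=t2, level=str(row.level).strip(), severity_group=group)
        )
    return DDIKnowledgeTable(entries=entries)


def read_pim_list(source: Source) -> PIMList:
    """Read the PIM reference list: one ATC term per line, ``#`` comments.

    An empty list is a contract violation — a caller reading the list is
    requesting the PIM analysis.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    terms: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            terms.add(validate_atc(line))
        except ValidationError as exc:
            raise ValidationError(f"pim_list line {lineno}: {exc}") from None
    if not terms:
        raise ValidationError("pim_list is empty; the PIM analysis needs at least one term")
    return PIMList(terms=frozenset(terms))


def filter_records_to_stays(
    records: Iterable[AdministrationRecord], stays: Iterable[StayRecord]
) -> list[AdministrationRecord]:
    """Drop administration rows outside their patient's stay window.

    Warehouse extracts commonly carry boundary artifacts (orders logged the
    day before admission, discharge prescriptions dated after the stay);
    these rows, and rows for patients without a stay record, are dropped with
    a logged warning rather than raising.
    """
    window = {s.patient_id: (s.admission_date, s.discharge_date) for s in stays}
    kept: list[AdministrationRecord] = []
    n_out, n_orphan = 0, 0
    for rec in records:
        if rec.patient_id not in window:
            n_orphan += 1
            continue
        lo, hi = window[rec.patient_id]
        if lo <= rec.date <= hi:
            kept.append(rec)
        else:
            n_out += 1
    if n_out:
        logger.warning("Dropped %d administration row(s) dated outside the stay window", n_out)
    if n_orphan:
        logger.warning("Dropped %d administration row(s) for patients with no stay record", n_orphan)
    return kept


# --------------------------------------------------------------------------
# Writers (round-trip of inputs; fixed dialect for outputs)
# --------------------------------------------------------------------------

#: CSV float rendering used for every output table (6 decimal places keeps
#: exposure-density ratios exact enough to re-read while making reruns
#: byte-identical).
FLOAT_FORMAT = "%.6f"


def write_table(frame: pd.DataFrame, path: Source) -> None:
    """Write an output table in the fixed dialect (UTF-8, comma, LF, %.6f)."""
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_administrations(records: Sequence[AdministrationRecord], path: Source) -> None:
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "atc_code": [r.atc_code for r in records],
            "drug_label": [r.drug_label or "" for r in records],
        }
    )
    write_table(frame, path)


def write_stays(stays: Sequence[StayRecord], path: Source) -> None:
    frame = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in stays],
            "admission_date": [s.admission_date.isoformat() for s in stays],
            "discharge_date": [s.discharge_date.isoformat() for s in stays],
            "transplant_date": [
                s.transplant_date.isoformat() if s.transplant_date else "" for s in stays
            ],
            "age_years": [s.age_years for s in stays],
        }
    )
    write_table(frame, path)


def write_ddi_table(table: DDIKnowledgeTable, path: Source) -> None:
    frame = pd.DataFrame(
        {
            "term1": [e.term1 for e in table.entries],
            "term2": [e.term2 for e in table.entries],
            "level": [e.level for e in table.entries],
        }
    )
    write_table(frame, path)


def write_pim_list(pims: PIMList, path: Source) -> None:
    text = "\n".join(sorted(pims.terms)) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text, encoding="utf-8")
    else:
        path.write(text)
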