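"""Synthetic medication-administration cohorts.

The generator emulates the in-hospital exposure structure of an autologous
stem-cell-transplant ward, where the analysis pipeline is most informative:
stays of two to seven weeks, a modest drug count at admission, a mid-stay
peak of supportive care that pushes most patients past the hyperpolypharmacy
threshold, a taper toward discharge, interaction-prone co-prescriptions
around the peak, pre-transplant conditioning chemotherapy (ATC class L01),
and chronic potentially-inappropriate medications in older patients.

Everything is reproducible from a single integer seed; each patient draws
from an independent substream keyed by (seed, patient index), so cohorts are
stable under reordering.  Alongside the records the generator emits a
*truth* structure — per-day counts, flags, interaction pairs and PIM hits
recomputed directly from the records it just wrote by straightforward
scanning loops — so the detection pipeline can be checked against planted
ground truth exactly.

A deterministic single-patient fixture with a hand-written daily drug-count
profile (34-day stay, polypharmacy on days 1-6, 10-25 and 27-28,
hyperpolypharmacy on days 15-21 only, 5 drugs on day 1, 1 drug at discharge)
exercises the worked example of the cumulative-exposure definitions.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records_io import (
    AdministrationRecord,
    DDIEntry,
    DDIKnowledgeTable,
    PIMList,
    StayRecord,
    ValidationError,
    validate_atc,
    write_administrations,
    write_ddi_table,
    write_pim_list,
    write_stays,
)

logger = logging.getLogger("cdexposure")

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "ATC_PALETTE",
    "toy_knowledge_tables",
    "generate_cohort",
    "figure1_fixture",
    "write_cohort",
]

_BASE_DATE = _dt.date(2021, 1, 4)

#: Hard-coded palette of syntactically valid ATC level-5 codes across classes
#: A, B, C, J, L and N.  The selection exercises the analysis paths
#: (antineoplastic L01 exclusion, interaction prefix matching at several ATC
#: levels, PIM prefix matching); pharmacological accuracy is not a goal.
ATC_PALETTE: tuple[str, ...] = (
    # A — alimentary tract and metabolism
    "A02BC01", "A02BC02", "A02BC05", "A04AA01", "A04AA02", "A06AB02",
    "A06AD11", "A07AA09", "A10BA02", "A12CC04",
    # B — blood
    "B01AB01", "B01AB05", "B01AC06", "B02BA01", "B05BA03", "B05XA03",
    # C — cardiovascular
    "C01CA03", "C03CA01", "C07AB02", "C08CA01", "C09AA05", "C10AA05",
    # J — anti-infectives
    "J01CR05", "J01DD04", "J01FA09", "J01MA02", "J01XA01", "J02AC01",
    "J02AX04", "J05AB01", "J05AB06", "J06BA02",
    # L — antineoplastics and immunomodulators
    "L01BC02", "L01CB01", "L01XX05", "L01AA01", "L03AA02", "L04AA06",
    # N — nervous system
    "N02AA01", "N02BE01", "N02AX02", "N03AE01", "N05BA01", "N05BA06",
    "N05CD08", "N06AB03", "N06AX11", "N07BC02",
)

#: Palette codes outside class L01, used where the conditioning-exclusion
#: path must stay inert.
_NON_L01 = tuple(c for c in ATC_PALETTE if not c.startswith("L01"))

#: Concrete level-5 code pairs that fire entries of the toy interaction
#: table, used for planting co-prescriptions near the exposure peak.
_PLANT_DDI_PAIRS: tuple[tuple[str, str], ...] = (
    ("C01CA03", "C07AB02"),   # contraindicated -> major
    ("N06AB03", "N02AA01"),   # should be avoided -> major
    ("A02BC05", "C03CA01"),   # precaution of use -> moderate
    ("B01AC06", "B01AB01"),   # precaution of use -> moderate
    ("N05BA01", "N02BE01"),   # to take into account -> moderate
)

#: Chronic PIM codes planted in older patients (each descends from a term of
#: the toy PIM list).
_PLANT_PIM_CODES: tuple[str, ...] = ("N05BA06", "N06AB03", "A02BC01", "N02AA01")


def toy_knowledge_tables() -> tuple[DDIKnowledgeTable, PIMList]:
    """Packaged stand-ins for a DDI knowledge base and a PIM reference list.

    The interaction table spans all four severity levels and mixes ATC term
    levels 2-5 so prefix matching is exercised; the PIM list mixes substance
    codes and class prefixes.
    """
    raw = [
        ("C01CA03", "C07AB02", "contraindicated"),
        ("L04AA06", "J02AC01", "contraindicated"),
        ("N06AB03", "N02AA01", "should_be_avoided"),
        ("J01FA09", "C01CA03", "should_be_avoided"),
        ("A02BC", "C03CA", "precaution_of_use"),     # level-4 prefixes
        ("B01AC06", "B01AB01", "precaution_of_use"),
        ("L01", "J02AC", "precaution_of_use"),       # level-2 x level-4
        ("C09AA05", "C03CA01", "precaution_of_use"),
        ("N05BA", "N02BE", "to_take_into_account"),  # level-4 prefixes
        ("C03C", "A12CC", "to_take_into_account"),   # level-3 prefix
        ("J01MA02", "A02BC05", "to_take_into_account"),
        ("N03AE01", "J05AB01", "to_take_into_account"),
    ]
    from .records_io import SEVERITY_GROUP

    entries = [
        DDIEntry(
            term1=validate_atc(t1),
            term2=validate_atc(t2),
            level=lvl,
            severity_group=SEVERITY_GROUP[lvl],
        )
        for t1, t2, lvl in raw
    ]
    pims = PIMList(
        terms=frozenset(
            validate_atc(t)
            for t in (
                "N05BA",      # benzodiazepines (class prefix)
                "N05CD08",
                "N02AA01",
                "N06AB03",
                "A02BC",      # proton-pump inhibitors (class prefix)
                "C07AB02",
                "N03AE01",
                "A06AB02",
                "J01MA02",
            )
        )
    )
    return DDIKnowledgeTable(entries=entries), pims


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings.

    Defaults mirror the transplant-ward use case: stays uniform on 14-52
    days, ages uniform on 21-70 (so roughly a third of patients reach the
    PIM age threshold), about 3 expected distinct drugs on the admission
    day rising linearly to about 12 at the peak (placed 45% of the way
    through the stay) and tapering to about 5 at discharge, the transplant
    placed a fifth of the way into the stay, interacting pairs co-prescribed
    on 60% of near-peak days, and 90% of older patients on a chronic PIM.
    Realized daily counts are Poisson around the expected profile.
    """

    n_patients: int = 69
    seed: int = 0
    los_min: int = 14
    los_max: int = 52
    age_min: int = 21
    age_max: int = 70
    admission_mean_drugs: float = 3.0
    peak_mean_drugs: float = 12.0
    discharge_mean_drugs: float = 5.0
    peak_position_frac: float = 0.45
    ddi_pair_rate: float = 0.6
    pim_rate_elderly: float = 0.9
    transplant_day_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if not (1 <= self.los_min <= self.los_max):
            raise ValidationError("need 1 <= los_min <= los_max")
        if not (0 <= self.age_min <= self.age_max):
            raise ValidationError("need 0 <= age_min <= age_max")
        for name in ("admission_mean_drugs", "peak_mean_drugs", "discharge_mean_drugs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("ddi_pair_rate", "pim_rate_elderly"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("peak_position_frac", "transplant_day_frac"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")


@dataclass
class SyntheticCohort:
    """Generated records plus per-day ground truth.

    ``truth`` maps patient_id to a dict with the generating intensities and
    the determinant state recomputed per day directly from the emitted
    records (keys: ``expected_drugs``, ``n_distinct``, ``pp``, ``hpp``,
    ``ddi_pairs``, ``pim_terms`` — the last is None for patients below the
    age threshold).
    """

    administrations: list[AdministrationRecord]
    stays: list[StayRecord]
    truth: dict = field(default_factory=dict)


def _expected_profile(cfg: CohortConfig, los: int) -> np.ndarray:
    """Piecewise-linear expected distinct-drug count per stay day."""
    if los == 1:
        return np.array([cfg.peak_mean_drugs])
    peak_day = int(round(cfg.peak_position_frac * (los - 1)))
    mu = np.empty(los)
    for d in range(los):
        if d <= peak_day:
            f = d / peak_day if peak_day else 1.0
            mu[d] = cfg.admission_mean_drugs + f * (cfg.peak_mean_drugs - cfg.admission_mean_drugs)
        else:
            f = (d - peak_day) / (los - 1 - peak_day)
            mu[d] = cfg.peak_mean_drugs + f * (cfg.discharge_mean_drugs - cfg.peak_mean_drugs)
    return mu


def _recount_truth(
    day_codes: list[set[str]],
    stay: StayRecord,
    kb: DDIKnowledgeTable,
    pims: PIMList,
    pim_age_min: int = 65,
) -> dict:
    """Recompute the determinant state per day by direct scanning.

    Intentionally a separate, plain-loop code path from the detection
    module, so planted-truth comparisons are meaningful.
    """
    pp_days, hpp_days, n_days, ddi_days, pim_days = [], [], [], [], []
    for offset, codes in enumerate(day_codes):
        date = stay.admission_date + _dt.timedelta(days=offset)
        pre_tx = stay.transplant_date is not None and date < stay.transplant_date
        counted = {c for c in codes if not (pre_tx and c.startswith("L01"))}
        n = len(counted)
        n_days.append(n)
        pp_days.append(n >= 5)
        hpp_days.append(n >= 10)
        pairs = {}
        for e in kb.entries:
            found = False
            for a in codes:
                for b in codes:
                    if a != b and a.startswith(e.term1) and b.startswith(e.term2):
                        found = True
            if found:
                key = tuple(sorted((e.term1, e.term2)))
                if key not in pairs or e.severity_group == "major":
                    pairs[key] = e.severity_group
        ddi_days.append(sorted([k[0], k[1], g] for k, g in pairs.items()))
        if stay.age_years >= pim_age_min:
            pim_days.append(sorted(t for t in pims.terms if any(c.startswith(t) for c in codes)))
        else:
            pim_days.append(None)
    return {
        "n_distinct": n_days,
        "pp": pp_days,
        "hpp": hpp_days,
        "ddi_pairs": ddi_days,
        "pim_terms": pim_days if stay.age_years >= pim_age_min else None,
    }


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort of the configured size, fully seeded.

    Per patient: a uniform stay length and age, a piecewise-linear
    admission→peak→discharge expected drug-count profile with Poisson
    realization, conditioning chemotherapy (L01) on pre-transplant days,
    interacting-pair co-prescriptions near the peak, and a chronic daily PIM
    in older patients.  The returned truth is recomputed from the emitted
    records (see :func:`_recount_truth`).
    """
    kb, pims = toy_knowledge_tables()
    cohort = SyntheticCohort(administrations=[], stays=[], truth={})
    for i in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        pid = f"P{i + 1:04d}"
        los = int(rng.integers(config.los_min, config.los_max + 1))
        age = int(rng.integers(config.age_min, config.age_max + 1))
        admission = _BASE_DATE + _dt.timedelta(days=i)
        discharge = admission + _dt.timedelta(days=los - 1)
        tx_offset = int(config.transplant_day_frac * los)
        transplant = admission + _dt.timedelta(days=tx_offset)
        stay = StayRecord(
            patient_id=pid,
            admission_date=admission,
            discharge_date=discharge,
            transplant_date=transplant,
            age_years=age,
        )

        mu = _expected_profile(config, los)
        peak_day = int(np.argmax(mu))
        window = max(1, los // 5)
        chronic_pim = None
        if age >= 65 and rng.random() < config.pim_rate_elderly:
            chronic_pim = str(rng.choice(_PLANT_PIM_CODES))

        day_codes: list[set[str]] = []
        for d in range(los):
            n_drugs = int(rng.poisson(mu[d]))
            take = min(n_drugs, len(_NON_L01))
            codes = set(
                rng.choice(_NON_L01, size=take, replace=False)
            ) if take else set()
            if d < tx_offset:
                # conditioning chemotherapy before the graft
                codes.add("L01" + str(rng.choice(("BC02", "CB01", "XX05", "AA01"))))
            if abs(d - peak_day) <= window and rng.random() < config.ddi_pair_rate:
                a, b = _PLANT_DDI_PAIRS[int(rng.integers(len(_PLANT_DDI_PAIRS)))]
                codes.update((a, b))
            if chronic_pim is not None:
                codes.add(chronic_pim)
            day_codes.append(codes)

        cohort.stays.append(stay)
        for d, codes in enumerate(day_codes):
            date = admission + _dt.timedelta(days=d)
            for code in sorted(codes):
                cohort.administrations.append(
                    AdministrationRecord(patient_id=pid, date=date, atc_code=code)
                )
        truth = _recount_truth(day_codes, stay, kb, pims)
        truth["expected_drugs"] = [float(v) for v in mu]
        truth["age_years"] = age
        truth["los_days"] = los
        truth["chronic_pim"] = chronic_pim
        cohort.truth[pid] = truth
    return cohort


#: Hand-written daily distinct-drug counts of the worked-example patient:
#: 34-day stay, exactly 5 drugs on day 1, polypharmacy (>=5) on days 1-6,
#: 10-25 and 27-28, hyperpolypharmacy (>=10) on days 15-21 only, exactly 1
#: drug on day 34.
_FIG1_COUNTS: tuple[int, ...] = (
    5, 6, 6, 6, 6, 6,          # days 1-6   : PP
    4, 4, 4,                   # days 7-9   : below threshold
    7, 7, 7, 7, 7,             # days 10-14 : PP
    11, 11, 12, 12, 11, 11, 11,  # days 15-21 : HPP
    8, 8, 7, 6,                # days 22-25 : PP
    4,                         # day 26     : below threshold
    5, 5,                      # days 27-28 : PP
    3, 3, 2, 2, 2,             # days 29-33 : below threshold
    1,                         # day 34     : discharge, 1 drug
)


def figure1_fixture() -> SyntheticCohort:
    """Deterministic single-patient worked-example cohort.

    The daily distinct-drug profile yields, through the pipeline, 24 days of
    cumulative exposure to polypharmacy, 7 days to hyperpolypharmacy, and a
    1→0 polypharmacy trajectory (present on the 5-drug admission day, absent
    on the 1-drug discharge day).  No transplant date and no L01 codes, so
    the conditioning exclusion is inert.  No randomness is involved.
    """
    pid = "F0001"
    admission = _dt.date(2021, 3, 1)
    los = len(_FIG1_COUNTS)
    stay = StayRecord(
        patient_id=pid,
        admission_date=admission,
        discharge_date=admission + _dt.timedelta(days=los - 1),
        transplant_date=None,
        age_years=60,
    )
    records: list[AdministrationRecord] = []
    day_codes: list[set[str]] = []
    for d, n in enumerate(_FIG1_COUNTS):
        codes = set(_NON_L01[:n])
        day_codes.append(codes)
        date = admission + _dt.timedelta(days=d)
        for code in sorted(codes):
            records.append(AdministrationRecord(patient_id=pid, date=date, atc_code=code))
    kb, pims = toy_knowledge_tables()
    truth = _recount_truth(day_codes, stay, kb, pims)
    truth["los_days"] = los
    truth["age_years"] = stay.age_years
    return SyntheticCohort(administrations=records, stays=[stay], truth={pid: truth})


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the four interchange files plus the ground truth.

    Emits ``administrations.csv``, ``stays.csv``, ``ddi_table.csv``,
    ``pim_list.txt`` (the packaged toy knowledge tables) and ``truth.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    kb, pims = toy_knowledge_tables()
    write_administrations(cohort.administrations, out / "administrations.csv")
    write_stays(cohort.stays, out / "stays.csv")
    write_ddi_table(kb, out / "ddi_table.csv")
    write_pim_list(pims, out / "pim_list.txt")
    (out / "truth.json").write_text(
        json.dumps(cohort.truth, indent=1, sort_keys=True), encoding="utf-8"
    )
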