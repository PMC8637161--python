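"""Domain record types for the claims-analysis pipeline.

Every record is a frozen dataclass that validates its own invariants on
construction; the readers in :mod:`polyrx.claims_io` catch the resulting
``ValueError`` per row and collect it into a rejects report instead of
failing the whole file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Optional

# ATC grammar: 1 letter (anatomical group), then optionally 2 digits,
# 1 letter, 1 letter, 2 digits.  Prefix truncations are legal codes at
# levels 1-4, so valid lengths are 1, 3, 4, 5 and 7 characters.
ATC_PATTERN = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

#: Character length of an ATC code truncated at each classification level.
ATC_LEVEL_LENGTH = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

#: Closed list of healthcare-service categories recognised in the
#: utilization table.
SERVICE_TYPES = (
    "Primary healthcare",
    "Outpatient specialist services",
    "Hospital treatment",
    "Medical rehabilitation",
    "Emergency medical services",
    "Psychiatric care and addiction treatment",
    "Services contracted separately",
    "Palliative and hospice care",
    "Nursing and care services",
    "Pilot programs",
)


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


def is_valid_atc(code: str) -> bool:
    """True iff ``code`` matches the ATC grammar (prefix truncations allowed)."""
    return bool(ATC_PATTERN.match(code))


@dataclass(frozen=True)
class DispensationRecord:
    """One reimbursed-drug dispensation event — the analysis's atomic input."""

    patient_id: str
    dispense_date: date
    atc_code: str
    packs: int
    ddd_per_pack: float
    prescriber_id: str = ""
    provider_id: str = ""
    encounter_id: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("empty patient_id")
        if self.packs < 1:
            raise ValueError("nonpositive packs")
        if not self.ddd_per_pack > 0:
            raise ValueError("nonpositive ddd_per_pack")
        if not is_valid_atc(self.atc_code):
            raise ValueError(f"malformed ATC code: {self.atc_code!r}")


@dataclass(frozen=True)
class PatientRecord:
    """Registry entry: demographics, region, and vital status of one patient."""

    patient_id: str
    birth_year: int
    sex: Sex = Sex.unknown
    county_code: str = ""
    voivodeship_code: str = ""
    death_date: Optional[date] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("empty patient_id")


@dataclass(frozen=True)
class UtilizationRecord:
    """One healthcare-service contact with its principal ICD-10 diagnosis."""

    patient_id: str
    service_type: str
    event_date: date
    icd10_code: str = ""
    is_hospitalisation: bool = False

    def __post_init__(self) -> None:
        if self.service_type not in SERVICE_TYPES:
            raise ValueError(f"unknown service type: {self.service_type!r}")


@dataclass(frozen=True)
class SupplyEvent:
    """A dispensation reduced to its start date and days of drug supply."""

    start_date: date
    supply_days: int

    def __post_init__(self) -> None:
        if self.supply_days < 1:
            raise ValueError("supply_days must be >= 1")


@dataclass
class CoverageTimeline:
    """Covered day-intervals of one patient-drug pair after carryover stitching.

    ``intervals`` is a sorted list of closed ``(first_day, last_day)`` date
    pairs, pairwise disjoint and non-adjacent (adjacent runs are merged).
    """

    patient_id: str
    drug_key: str
    intervals: list = field(default_factory=list)

    @property
    def covered_days(self) -> int:
        return sum((b - a).days + 1 for a, b in self.intervals)

    def covers(self, day: date) -> bool:
        return any(a <= day <= b for a, b in self.intervals)


@dataclass(frozen=True)
class MonthlyStatus:
    """Per patient-calendar-month concurrency coverage and qualification flag."""

    patient_id: str
    month: str  # "YYYY-MM"
    days_in_month: int
    days_at_or_above_threshold: int
    coverage_fraction: float
    qualifies: bool

    def __post_init__(self) -> None:
        if not 28 <= self.days_in_month <= 31:
            raise ValueError("days_in_month out of civil-calendar range")
        if not 0 <= self.days_at_or_above_threshold <= self.days_in_month:
            raise ValueError("qualifying days exceed month length")


@dataclass(frozen=True)
class PolypharmacyLabel:
    """Per-patient basic/chronic/whole-year classification with supporting counts."""

    patient_id: str
    is_elderly: bool
    basic_polypharmacy: bool
    chronic_polypharmacy: bool
    longest_qualifying_run_months: int
    whole_year: bool
    distinct_drugs_6m: int
    first_dispense_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.longest_qualifying_run_months < 0:
            raise ValueError("negative qualifying run")
        if self.whole_year and not self.chronic_polypharmacy:
            raise ValueError("whole_year requires chronic_polypharmacy")
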