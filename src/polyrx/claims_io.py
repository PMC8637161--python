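"""Read, validate and write the pipeline's tables.

Canonical format is delimited text: CSV, UTF-8, ISO-8601 dates. Real
claims extracts are dirty, so malformed rows are rejected individually
with a reason (not a whole-file failure) and collected into a
machine-readable rejects report; a missing mandatory column is a fatal
schema error. Every reader logs accepted/rejected counts, and
rejected + accepted always equals the input row count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .config import AnalysisConfig
from .records import (
    DispensationRecord,
    MonthlyStatus,
    PatientRecord,
    PolypharmacyLabel,
    Sex,
    UtilizationRecord,
)

logger = logging.getLogger("polyrx")

CLAIMS_COLUMNS = (
    "patient_id", "dispense_date", "atc_code", "packs", "ddd_per_pack",
    "prescriber_id", "provider_id", "encounter_id",
)
PATIENT_COLUMNS = (
    "patient_id", "birth_year", "sex", "county_code", "voivodeship_code", "death_date",
)
UTILIZATION_COLUMNS = (
    "patient_id", "service_type", "event_date", "icd10_code", "is_hospitalisation",
)
LABEL_COLUMNS = (
    "patient_id", "is_elderly", "basic_polypharmacy", "chronic_polypharmacy",
    "longest_qualifying_run_months", "whole_year", "distinct_drugs_6m",
    "first_dispense_date",
)


class SchemaError(ValueError):
    """A mandatory column is missing — the file cannot be interpreted."""


@dataclass(frozen=True)
class RejectedRow:
    row: int  # 0-based data-row index, header excluded
    reason: str
    data: dict


@dataclass
class ReadResult:
    """Accepted records plus the rejects report for one input file."""

    records: list
    rejects: List[RejectedRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df


def _parse_date(token: str) -> date:
    return date.fromisoformat(token.strip())


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise ValueError(f"unparseable boolean: {token!r}")


def read_claims(path, config: Optional[AnalysisConfig] = None) -> ReadResult:
    """Parse a dispensation-claims CSV into records.

    Row-level checks: ISO date inside the study year (or its pre-year
    lookback window), positive integer packs, positive DDD content, and a
    grammatical ATC code. Failing rows go to the rejects report with a
    reason tag.
    """
    config = config or AnalysisConfig()
    df = _read_table(path, CLAIMS_COLUMNS[:5])
    window_start = date(config.study_year, 1, 1) - timedelta(days=config.lookback_days)
    window_end = date(config.study_year, 12, 31)
    records: List[DispensationRecord] = []
    rejects: List[RejectedRow] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        try:
            d = _parse_date(raw["dispense_date"])
        except ValueError:
            rejects.append(RejectedRow(i, "unparseable date", raw))
            continue
        if not window_start <= d <= window_end:
            rejects.append(RejectedRow(i, "date outside study window", raw))
            continue
        try:
            packs = int(raw["packs"])
        except ValueError:
            rejects.append(RejectedRow(i, "unparseable packs", raw))
            continue
        if packs < 1:
            rejects.append(RejectedRow(i, "nonpositive packs", raw))
            continue
        try:
            ddd = float(raw["ddd_per_pack"])
        except ValueError:
            rejects.append(RejectedRow(i, "unparseable ddd_per_pack", raw))
            continue
        try:
            rec = DispensationRecord(
                patient_id=raw["patient_id"].strip(),
                dispense_date=d,
                atc_code=raw["atc_code"].strip().upper(),
                packs=packs,
                ddd_per_pack=ddd,
                prescriber_id=raw.get("prescriber_id", "").strip(),
                provider_id=raw.get("provider_id", "").strip(),
                encounter_id=raw.get("encounter_id", "").strip(),
            )
        except ValueError as exc:
            rejects.append(RejectedRow(i, str(exc), raw))
            continue
        records.append(rec)
    logger.info("read_claims: %s accepted=%d rejected=%d", path, len(records), len(rejects))
    assert len(records) + len(rejects) == len(df)
    return ReadResult(records=records, rejects=rejects)


_SEX_TOKENS = {
    "m": Sex.male, "male": Sex.male,
    "f": Sex.female, "female": Sex.female,
    "u": Sex.unknown, "unknown": Sex.unknown, "": Sex.unknown,
}


def read_patients(path) -> Dict[str, PatientRecord]:
    """Parse the patient registry; one record per unique patient_id.

    A duplicated id is fatal. An unrecognised sex token maps to
    ``unknown`` with a warning.
    """
    df = _read_table(path, PATIENT_COLUMNS[:3])
    registry: Dict[str, PatientRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        pid = raw["patient_id"].strip()
        if pid in registry:
            raise ValueError(f"duplicate patient_id {pid!r} at data row {i}")
        token = raw.get("sex", "").strip().lower()
        if token not in _SEX_TOKENS:
            warnings.warn(f"unknown sex token {raw.get('sex')!r} for {pid}; recorded as unknown")
        sex = _SEX_TOKENS.get(token, Sex.unknown)
        dd = raw.get("death_date", "").strip()
        registry[pid] = PatientRecord(
            patient_id=pid,
            birth_year=int(raw["birth_year"]),
            sex=sex,
            county_code=raw.get("county_code", "").strip(),
            voivodeship_code=raw.get("voivodeship_code", "").strip(),
            death_date=_parse_date(dd) if dd else None,
        )
    logger.info("read_patients: %s n=%d", path, len(registry))
    return registry


def read_utilization(path) -> ReadResult:
    """Parse the healthcare-utilization table; rows with a service type
    outside the closed category list are rejected."""
    df = _read_table(path, UTILIZATION_COLUMNS[:3])
    records: List[UtilizationRecord] = []
    rejects: List[RejectedRow] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        try:
            rec = UtilizationRecord(
                patient_id=raw["patient_id"].strip(),
                service_type=raw["service_type"].strip(),
                event_date=_parse_date(raw["event_date"]),
                icd10_code=raw.get("icd10_code", "").strip(),
                is_hospitalisation=_parse_bool(raw.get("is_hospitalisation", "")),
            )
        except ValueError as exc:
            rejects.append(RejectedRow(i, str(exc), raw))
            continue
        records.append(rec)
    logger.info("read_utilization: %s accepted=%d rejected=%d", path, len(records), len(rejects))
    return ReadResult(records=records, rejects=rejects)


# ---------------------------------------------------------------------------
# writers (round-trip property: write then read is the identity)

def _bool_token(b: bool) -> str:
    return "true" if b else "false"


def write_labels(labels: Iterable[PolypharmacyLabel], path) -> None:
    rows = [
        {
            "patient_id": l.patient_id,
            "is_elderly": _bool_token(l.is_elderly),
            "basic_polypharmacy": _bool_token(l.basic_polypharmacy),
            "chronic_polypharmacy": _bool_token(l.chronic_polypharmacy),
            "longest_qualifying_run_months": l.longest_qualifying_run_months,
            "whole_year": _bool_token(l.whole_year),
            "distinct_drugs_6m": l.distinct_drugs_6m,
            "first_dispense_date": l.first_dispense_date.isoformat() if l.first_dispense_date else "",
        }
        for l in labels
    ]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def read_labels(path) -> List[PolypharmacyLabel]:
    df = _read_table(path, LABEL_COLUMNS)
    labels = []
    for row in df.itertuples(index=False):
        raw = dict(zip(df.columns, row))
        fd = raw["first_dispense_date"].strip()
        labels.append(
            PolypharmacyLabel(
                patient_id=raw["patient_id"],
                is_elderly=_parse_bool(raw["is_elderly"]),
                basic_polypharmacy=_parse_bool(raw["basic_polypharmacy"]),
                chronic_polypharmacy=_parse_bool(raw["chronic_polypharmacy"]),
                longest_qualifying_run_months=int(raw["longest_qualifying_run_months"]),
                whole_year=_parse_bool(raw["whole_year"]),
                distinct_drugs_6m=int(raw["distinct_drugs_6m"]),
                first_dispense_date=_parse_date(fd) if fd else None,
            )
        )
    return labels


def write_claims(records: Iterable[DispensationRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "dispense_date": r.dispense_date.isoformat(),
            "atc_code": r.atc_code,
            "packs": r.packs,
            "ddd_per_pack": r.ddd_per_pack,
            "prescriber_id": r.prescriber_id,
            "provider_id": r.provider_id,
            "encounter_id": r.encounter_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CLAIMS_COLUMNS).to_csv(path, index=False)


def write_patients(patients: Iterable[PatientRecord], path) -> None:
    pats = patients.values() if isinstance(patients, dict) else patients
    rows = [
        {
            "patient_id": p.patient_id,
            "birth_year": p.birth_year,
            "sex": p.sex.value,
            "county_code": p.county_code,
            "voivodeship_code": p.voivodeship_code,
            "death_date": p.death_date.isoformat() if p.death_date else "",
        }
        for p in pats
    ]
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def write_utilization(records: Iterable[UtilizationRecord], path) -> None:
    rows = [
        {
            "patient_id": u.patient_id,
            "service_type": u.service_type,
            "event_date": u.event_date.isoformat(),
            "icd10_code": u.icd10_code,
            "is_hospitalisation": _bool_token(u.is_hospitalisation),
        }
        for u in records
    ]
    pd.DataFrame(rows, columns=UTILIZATION_COLUMNS).to_csv(path, index=False)


def write_monthly_statuses(statuses: Iterable[MonthlyStatus], path) -> None:
    rows = [
        {
            "patient_id": s.patient_id,
            "month": s.month,
            "days_in_month": s.days_in_month,
            "qualifying_days": s.days_at_or_above_threshold,
            "fraction": s.coverage_fraction,
            "qualifies": _bool_token(s.qualifies),
        }
        for s in statuses
    ]
    pd.DataFrame(
        rows,
        columns=["patient_id", "month", "days_in_month", "qualifying_days", "fraction", "qualifies"],
    ).to_csv(path, index=False)


def write_rejects(rejects: Iterable[RejectedRow], path) -> None:
    rows = [{"row": r.row, "reason": r.reason, **{f"in_{k}": v for k, v in r.data.items()}} for r in rejects]
    pd.DataFrame(rows).to_csv(path, index=False)
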