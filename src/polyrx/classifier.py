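"""Per-patient polypharmacy labels.

Three nested labels are produced for each registry patient:

* **basic polypharmacy** — at least ``min_drugs`` distinct drugs (ATC
  level-5 keys) dispensed within 183 days (half-open) of the patient's
  first dispensation in the calendar year;
* **chronic polypharmacy** — a run of at least ``chronic_window_months``
  consecutive calendar months in which the patient possessed
  ``min_drugs`` or more drugs on >= 80% of days;
* **whole-year persistence** — all twelve months qualify.

Two readings of the monthly criterion are implemented. The default
``day_concurrency`` mode counts, day by day, how many distinct drugs are
concurrently possessed and requires that count to reach ``min_drugs`` on
>= 80% of the month's days. The alternative ``per_drug`` mode requires at
least ``min_drugs`` drugs to *each* be possessed on >= 80% of the month's
days. Day-level concurrency is the stricter and is the default.

Months after a patient's death cannot qualify: coverage is clipped at the
death date before concurrency is computed.
"""

from __future__ import annotations

import calendar
import logging
from collections import defaultdict
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .atc_rules import AtcExclusionList, concurrency_key, filter_claims
from .config import AnalysisConfig
from .possession import (
    clip_timeline,
    coverage_qualifies,
    covered_days_in_month,
    daily_concurrency,
    timelines_from_claims,
    year_statuses,
)
from .records import (
    DispensationRecord,
    MonthlyStatus,
    PatientRecord,
    PolypharmacyLabel,
    Sex,
)

logger = logging.getLogger("polyrx")

BASIC_WINDOW_DAYS = 183  # six months, half-open


def classify_basic(
    records: Sequence[DispensationRecord],
    config: AnalysisConfig,
) -> Tuple[bool, int, Optional[date]]:
    """Basic polypharmacy: distinct drug keys dispensed within 183 days of
    the first dispensation of the calendar year.

    Records must already be ATC-filtered. Lookback-window rows (before
    January 1 of the study year) are ignored here: the anchor is the first
    dispensation *in* the year.
    """
    year_start = date(config.study_year, 1, 1)
    in_year = [r for r in records if r.dispense_date >= year_start]
    if not in_year:
        return False, 0, None
    first = min(r.dispense_date for r in in_year)
    window_end = first + timedelta(days=BASIC_WINDOW_DAYS)
    keys = {
        concurrency_key(r.atc_code)
        for r in in_year
        if first <= r.dispense_date < window_end
    }
    return len(keys) >= config.min_drugs, len(keys), first


def longest_true_run(flags: Sequence[bool]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def classify_chronic(
    statuses: Optional[Sequence[MonthlyStatus]] = None,
    *,
    config: AnalysisConfig,
    mode: str = "day_concurrency",
    per_drug_monthly_days: Optional[Mapping[str, Sequence[int]]] = None,
) -> Tuple[bool, int]:
    """Chronic polypharmacy from twelve monthly qualification flags.

    ``day_concurrency`` mode consumes the January..December
    :class:`MonthlyStatus` list. ``per_drug`` mode instead consumes, per
    drug key, the twelve monthly covered-day counts, and a month qualifies
    when >= ``min_drugs`` drugs each reach the coverage threshold.
    Returns ``(chronic, longest_qualifying_run)``.
    """
    if mode == "day_concurrency":
        if statuses is None or len(statuses) < 12:
            raise ValueError("need 12 monthly statuses (January..December)")
        flags = [s.qualifies for s in statuses[:12]]
    elif mode == "per_drug":
        if per_drug_monthly_days is None:
            raise ValueError("per_drug mode needs per-drug monthly covered-day counts")
        dims = [calendar.monthrange(config.study_year, m)[1] for m in range(1, 13)]
        flags = []
        for i, dim in enumerate(dims):
            n_ok = sum(
                1
                for days in per_drug_monthly_days.values()
                if coverage_qualifies(days[i], dim, config)
            )
            flags.append(n_ok >= config.min_drugs)
    else:
        raise ValueError(f"unknown chronic mode: {mode!r}")
    run = longest_true_run(flags)
    return run >= config.chronic_window_months, run


def classify_patient(
    records: Sequence[DispensationRecord],
    patient: PatientRecord,
    config: AnalysisConfig,
    mode: Optional[str] = None,
) -> Tuple[PolypharmacyLabel, List[MonthlyStatus]]:
    """Full label for one patient from their ATC-filtered claims."""
    mode = mode or config.chronic_mode
    year = config.study_year
    basic, n_distinct, first = classify_basic(records, config)

    timelines = timelines_from_claims(records, config) if records else []
    if patient.death_date is not None:
        timelines = [clip_timeline(tl, patient.death_date) for tl in timelines]
        timelines = [tl for tl in timelines if tl.intervals]

    window = (date(year, 1, 1), date(year, 12, 31))
    series = daily_concurrency(timelines, window)
    statuses = year_statuses(series, year, config, patient_id=patient.patient_id)

    if mode == "per_drug":
        per_drug = {
            tl.drug_key: [covered_days_in_month(tl, year, m) for m in range(1, 13)]
            for tl in timelines
        }
        chronic, run = classify_chronic(
            config=config, mode="per_drug", per_drug_monthly_days=per_drug
        )
    else:
        chronic, run = classify_chronic(statuses, config=config, mode="day_concurrency")

    age = year - patient.birth_year
    label = PolypharmacyLabel(
        patient_id=patient.patient_id,
        is_elderly=age >= config.elderly_age_cutoff,
        basic_polypharmacy=basic,
        chronic_polypharmacy=chronic,
        longest_qualifying_run_months=run,
        whole_year=chronic and run >= 12,
        distinct_drugs_6m=n_distinct,
        first_dispense_date=first,
    )
    return label, statuses


@dataclass
class PipelineResult:
    """Labels plus the per-patient monthly-status table behind them."""

    labels: List[PolypharmacyLabel]
    statuses: List[MonthlyStatus]
    n_claims_in: int = 0
    n_claims_used: int = 0
    n_unknown_patient: int = 0

    def labels_by_id(self) -> Dict[str, PolypharmacyLabel]:
        return {l.patient_id: l for l in self.labels}


def classify_cohort(
    claims: Iterable[DispensationRecord],
    patients: Mapping[str, PatientRecord],
    config: AnalysisConfig,
    mode: Optional[str] = None,
) -> PipelineResult:
    """Classify every registry patient; deterministic and independent of
    claim row order.

    Patients with no claims get all-false labels. Claims referencing a
    patient absent from the registry are rejected by default, or
    auto-registered (birth year unknown -> never elderly) when
    ``unknown_patient_policy`` is ``"register"``.
    """
    claims = list(claims)
    rules = AtcExclusionList.from_prefixes(config.excluded_atc_prefixes)
    filtered = filter_claims(claims, rules)

    registry: Dict[str, PatientRecord] = dict(patients)
    by_patient: Dict[str, List[DispensationRecord]] = defaultdict(list)
    unknown = 0
    for r in filtered:
        if r.patient_id not in registry:
            if config.unknown_patient_policy == "register":
                registry[r.patient_id] = PatientRecord(
                    patient_id=r.patient_id, birth_year=config.study_year, sex=Sex.unknown
                )
            else:
                unknown += 1
                continue
        by_patient[r.patient_id].append(r)

    labels: List[PolypharmacyLabel] = []
    statuses: List[MonthlyStatus] = []
    for pid in sorted(registry):
        label, st = classify_patient(by_patient.get(pid, []), registry[pid], config, mode)
        labels.append(label)
        statuses.extend(st)

    logger.info(
        "classify_cohort: claims_in=%d after_atc_filter=%d unknown_patient=%d patients=%d chronic=%d",
        len(claims), len(filtered), unknown, len(labels),
        sum(l.chronic_polypharmacy for l in labels),
    )
    return PipelineResult(
        labels=labels,
        statuses=statuses,
        n_claims_in=len(claims),
        n_claims_used=len(filtered) - unknown,
        n_unknown_patient=unknown,
    )
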