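"""Possession engine: dispensations -> covered-day timelines -> daily
concurrent-drug counts -> per-calendar-month coverage status.

The central quantity is *possession*: a day on which the patient holds
dispensed supply of a drug. Supply duration comes from the dispensed DDD
content divided by the assumed daily consumption (default 1 DDD/day). Two
carryover policies are provided:

``shift_forward``
    An early refill is stockpiled: its supply begins the day after the
    prior supply ends, so total covered days per drug always equal the
    total dispensed supply (the standard PDC convention).
``truncate``
    Each dispensation covers ``[start, start + supply_days - 1]`` and
    overlapping supply is simply unioned (overlap days are lost).

A calendar month *qualifies* when the number of days with at least
``min_drugs`` concurrently possessed drugs reaches the coverage threshold
(default 80% of the month's days). The >= comparison is done by integer
cross-multiplication on exact rationals, so there is no floating-point
ambiguity at the boundary.
"""

from __future__ import annotations

import calendar
from datetime import date, timedelta
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .records import CoverageTimeline, DispensationRecord, MonthlyStatus, SupplyEvent


def supply_days(record: DispensationRecord, config: AnalysisConfig) -> int:
    """Days of supply in one dispensation: floor(packs x DDD-per-pack /
    assumed daily DDD), with a minimum of one day so every dispensation
    contributes."""
    if record.packs < 1 or record.ddd_per_pack <= 0:
        raise ValueError("nonpositive packs or DDD content")
    if config.assumed_daily_ddd <= 0:
        raise ValueError("nonpositive assumed_daily_ddd")
    days = int(record.packs * record.ddd_per_pack / config.assumed_daily_ddd)
    return max(days, 1)


def _merge(intervals: List[Tuple[date, date]]) -> List[Tuple[date, date]]:
    """Merge overlapping or adjacent closed intervals into canonical form."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for a, b in intervals[1:]:
        la, lb = merged[-1]
        if a <= lb + timedelta(days=1):
            if b > lb:
                merged[-1] = (la, b)
        else:
            merged.append((a, b))
    return merged


def build_timeline(
    events: Iterable[SupplyEvent],
    policy: str = "shift_forward",
    *,
    patient_id: str = "",
    drug_key: str = "",
) -> CoverageTimeline:
    """Stitch one patient-drug pair's supply events into covered intervals.

    Intervals are unclipped (they may extend past any study horizon);
    clipping for monthly statistics happens downstream so the
    supply-conservation property of ``shift_forward`` stays checkable.
    """
    evs = sorted(events, key=lambda e: (e.start_date, e.supply_days))
    raw: List[Tuple[date, date]] = []
    if policy == "shift_forward":
        next_free: date | None = None
        for e in evs:
            start = e.start_date
            if next_free is not None and next_free > start:
                start = next_free
            end = start + timedelta(days=e.supply_days - 1)
            raw.append((start, end))
            next_free = end + timedelta(days=1)
    elif policy == "truncate":
        raw = [(e.start_date, e.start_date + timedelta(days=e.supply_days - 1)) for e in evs]
    else:
        raise ValueError(f"unknown carryover policy: {policy!r}")
    return CoverageTimeline(patient_id=patient_id, drug_key=drug_key, intervals=_merge(raw))


def clip_timeline(timeline: CoverageTimeline, last_day: date) -> CoverageTimeline:
    """Remove coverage after ``last_day`` (e.g. the patient's death date)."""
    clipped = [(a, min(b, last_day)) for a, b in timeline.intervals if a <= last_day]
    return CoverageTimeline(timeline.patient_id, timeline.drug_key, clipped)


def daily_concurrency(
    timelines: Iterable[CoverageTimeline],
    window: Tuple[date, date],
) -> pd.Series:
    """Per-day count of distinct drugs covered, over a closed date window.

    Returns an integer Series indexed by calendar day. Timelines must all
    belong to one patient (one entry per drug key).
    """
    start, end = window
    if end < start:
        raise ValueError("window end precedes start")
    n = (end - start).days + 1
    counts = np.zeros(n, dtype=np.int64)
    for tl in timelines:
        for a, b in tl.intervals:
            lo = max(a, start)
            hi = min(b, end)
            if lo <= hi:
                counts[(lo - start).days : (hi - start).days + 1] += 1
    return pd.Series(counts, index=pd.date_range(start, end, freq="D"))


def coverage_qualifies(qualifying_days: int, days_in_month: int, config: AnalysisConfig) -> bool:
    """Exact >= test: qualifying_days / days_in_month >= threshold, by
    integer cross-multiplication (e.g. days x 5 >= 4 x days_in_month for 0.8)."""
    thr = config.threshold_fraction
    return qualifying_days * thr.denominator >= thr.numerator * days_in_month


def monthly_status(
    series: pd.Series,
    month: str | Tuple[int, int],
    config: AnalysisConfig,
    *,
    patient_id: str = "",
) -> MonthlyStatus:
    """Qualification status of one calendar month from a per-day count series.

    ``month`` is ``"YYYY-MM"`` or a ``(year, month)`` pair; the series must
    cover every day of that month.
    """
    if isinstance(month, str):
        year, mm = (int(p) for p in month.split("-"))
    else:
        year, mm = month
    key = f"{year:04d}-{mm:02d}"
    dim = calendar.monthrange(year, mm)[1]
    if not isinstance(series.index, pd.DatetimeIndex):
        raise ValueError("series must be indexed by calendar day")
    try:
        sub = series.loc[key]
    except KeyError:
        raise ValueError(f"series does not cover the month {key}") from None
    if np.isscalar(sub) or len(sub) < dim:
        raise ValueError(f"series does not cover the whole month {key}")
    qualifying = int((sub.to_numpy() >= config.min_drugs).sum())
    return MonthlyStatus(
        patient_id=patient_id,
        month=key,
        days_in_month=dim,
        days_at_or_above_threshold=qualifying,
        coverage_fraction=qualifying / dim,
        qualifies=coverage_qualifies(qualifying, dim, config),
    )


def year_statuses(
    series: pd.Series,
    year: int,
    config: AnalysisConfig,
    *,
    patient_id: str = "",
) -> List[MonthlyStatus]:
    """January..December monthly statuses for one patient's concurrency series."""
    return [monthly_status(series, (year, m), config, patient_id=patient_id) for m in range(1, 13)]


def covered_days_in_month(timeline: CoverageTimeline, year: int, month: int) -> int:
    """Days of the given calendar month covered by the timeline."""
    dim = calendar.monthrange(year, month)[1]
    first, last = date(year, month, 1), date(year, month, dim)
    total = 0
    for a, b in timeline.intervals:
        lo, hi = max(a, first), min(b, last)
        if lo <= hi:
            total += (hi - lo).days + 1
    return total


def timelines_from_claims(
    records: Sequence[DispensationRecord],
    config: AnalysisConfig,
    *,
    level: int = 5,
) -> List[CoverageTimeline]:
    """Group one patient's claims by drug key and build each drug's timeline."""
    from .atc_rules import concurrency_key

    by_drug: dict[str, list[SupplyEvent]] = {}
    patient = records[0].patient_id if records else ""
    for r in records:
        key = concurrency_key(r.atc_code, level)
        by_drug.setdefault(key, []).append(
            SupplyEvent(start_date=r.dispense_date, supply_days=supply_days(r, config))
        )
    return [
        build_timeline(evs, config.carryover_policy, patient_id=patient, drug_key=key)
        for key, evs in sorted(by_drug.items())
    ]
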