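"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the interval arithmetic of the package:
coverage is simulated day by day (a stock counter that refills on
dispensing days and decrements when consumed), so agreement between the
two routes is a real cross-check.
"""

from __future__ import annotations

from collections import Counter
from datetime import date, timedelta

import pytest

from polyrx import AnalysisConfig
from polyrx.records import SupplyEvent


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def bruteforce_covered_days(events, policy: str) -> set:
    """Day-by-day simulation of drug possession for one patient-drug pair."""
    events = list(events)
    if not events:
        return set()
    covered = set()
    if policy == "shift_forward":
        start = min(e.start_date for e in events)
        end = max(e.start_date for e in events) + timedelta(
            days=sum(e.supply_days for e in events) + 1
        )
        stock = 0
        day = start
        while day <= end:
            stock += sum(e.supply_days for e in events if e.start_date == day)
            if stock > 0:
                covered.add(day)
                stock -= 1
            day += timedelta(days=1)
    elif policy == "truncate":
        for e in events:
            for k in range(e.supply_days):
                covered.add(e.start_date + timedelta(days=k))
    else:
        raise ValueError(policy)
    return covered


def bruteforce_concurrency(per_drug_events, window, policy: str) -> dict:
    """Per-day distinct-drug count from the day-by-day possession oracle."""
    lo, hi = window
    counter: Counter = Counter()
    for events in per_drug_events.values():
        for day in bruteforce_covered_days(events, policy):
            if lo <= day <= hi:
                counter[day] += 1
    n = (hi - lo).days + 1
    return {lo + timedelta(days=k): counter.get(lo + timedelta(days=k), 0) for k in range(n)}


def random_patient_events(rng, year: int = 2018, max_drugs: int = 20, max_events: int = 30):
    """Random per-drug supply events for one synthetic stress-test patient."""
    n_drugs = int(rng.integers(1, max_drugs + 1))
    per_drug = {}
    for d in range(n_drugs):
        n_ev = int(rng.integers(1, max_events + 1))
        events = []
        for _ in range(n_ev):
            start = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
            events.append(SupplyEvent(start_date=start, supply_days=int(rng.integers(1, 61))))
        per_drug[f"D{d:02d}"] = events
    return per_drug
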