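"""Analysis configuration.

All thresholds of the operational polypharmacy definition live here so a
sensitivity analysis is a config edit, not a code change:

* ``min_drugs`` — concurrent-drug threshold (5 = the conventional
  polypharmacy cut-off);
* ``coverage_threshold`` — fraction of a month's days that must be at or
  above ``min_drugs`` for the month to qualify (0.8, the usual PDC
  adherence cut-off);
* ``chronic_window_months`` — consecutive qualifying months required for
  the chronic label (6);
* ``assumed_daily_ddd`` — assumed consumption rate converting dispensed
  DDDs into days of supply (1 DDD/day, the WHO drug-utilization
  convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional

import yaml

#: ATC prefixes excluded from the drug count: short-term / topical therapy
#: groups of no importance for chronic treatment (stomatological
#: preparations, laxatives, dermatologicals, anti-infectives, immune sera,
#: vaccines, ectoparasiticides, various).
DEFAULT_EXCLUDED_ATC_PREFIXES = (
    "A01", "A06", "D", "J01", "J02", "J05", "J06", "J07", "P03", "V",
)

CARRYOVER_POLICIES = ("shift_forward", "truncate")
CHRONIC_MODES = ("day_concurrency", "per_drug")


@dataclass(frozen=True)
class AnalysisConfig:
    study_year: int = 2018
    min_drugs: int = 5
    coverage_threshold: float = 0.8
    chronic_window_months: int = 6
    elderly_age_cutoff: int = 65
    assumed_daily_ddd: float = 1.0
    excluded_atc_prefixes: tuple = DEFAULT_EXCLUDED_ATC_PREFIXES
    carryover_policy: str = "shift_forward"
    chronic_mode: str = "day_concurrency"
    lookback_days: int = 0
    unknown_patient_policy: str = "reject"  # or "register"
    ddd_daily_denominator: str = "days_observed"  # or "full_year"
    rounding_decimals: int = 1
    sd_ddof: int = 1  # sample standard deviation by default

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.min_drugs < 1:
            raise ValueError("min_drugs must be >= 1")
        if self.chronic_window_months < 1:
            raise ValueError("chronic_window_months must be >= 1")
        if self.assumed_daily_ddd <= 0:
            raise ValueError("assumed_daily_ddd must be positive")
        if self.lookback_days < 0:
            raise ValueError("lookback_days must be >= 0")
        if self.carryover_policy not in CARRYOVER_POLICIES:
            raise ValueError(f"unknown carryover_policy: {self.carryover_policy!r}")
        if self.chronic_mode not in CHRONIC_MODES:
            raise ValueError(f"unknown chronic_mode: {self.chronic_mode!r}")
        if self.unknown_patient_policy not in ("reject", "register"):
            raise ValueError("unknown_patient_policy must be 'reject' or 'register'")
        if self.ddd_daily_denominator not in ("days_observed", "full_year"):
            raise ValueError("ddd_daily_denominator must be 'days_observed' or 'full_year'")

    @property
    def threshold_fraction(self) -> Fraction:
        """Coverage threshold as an exact rational, for tolerance-free
        integer cross-multiplication at the >= boundary."""
        return Fraction(str(self.coverage_threshold))

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_atc_prefixes"] = list(self.excluded_atc_prefixes)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        if "excluded_atc_prefixes" in data:
            data["excluded_atc_prefixes"] = tuple(data["excluded_atc_prefixes"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class ExternalDenominators:
    """Population denominators for prevalence rates.

    Defaults are the 2018 Polish public statistics: total population and
    citizens aged over 65 years. Per-region population tables are optional;
    regions without an entry get counts but no rates.
    """

    national_population: int = 38_411_148
    elderly_population: int = 6_732_360
    county_populations: Optional[dict] = None
    voivodeship_populations: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.national_population <= 0 or self.elderly_population <= 0:
            raise ValueError("population denominators must be positive")
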