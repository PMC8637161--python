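"""Descriptive cohort summaries of the chronic-polypharmacy population.

Everything here is arithmetic on counts: prevalence percentages with
explicit numerators and denominators, the monthly qualification series,
demographic and regional tables, prescriber/encounter/provider contact
distributions, DDD consumption statistics, top-drug rankings, and
healthcare-utilization tables. Percentages are rounded half-up to one
decimal by default and every stored percentage is re-derivable from its
stored numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .atc_rules import AtcExclusionList, concurrency_key, filter_claims
from .config import AnalysisConfig, ExternalDenominators
from .records import (
    DispensationRecord,
    MonthlyStatus,
    PatientRecord,
    PolypharmacyLabel,
    SERVICE_TYPES,
    Sex,
    UtilizationRecord,
)

logger = logging.getLogger("polyrx")

#: Age bands used for the chronic-cohort demographic table.
AGE_BANDS: Tuple[Tuple[int, Optional[int]], ...] = (
    (65, 69), (70, 74), (75, 79), (80, 84), (85, 89), (90, 94), (95, None),
)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 decimal rounds to 0.1, not 0.0)."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """numerator / denominator x 100, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, decimals)


def verify_ratio(numerator: int, denominator: int, printed_value: float, decimals: int = 1) -> bool:
    """Does a printed percentage agree with its printed numerator and
    denominator at the printed precision? Used to flag internally
    inconsistent published cells rather than matching them."""
    return pct(numerator, denominator, decimals) == round_half_up(printed_value, decimals)


# ---------------------------------------------------------------------------
# elementary statistics

@dataclass(frozen=True)
class DistributionStats:
    mean: float
    sd: float
    median: float
    histogram: Mapping[int, int]
    n: int


def distribution_stats(values: Sequence[float], ddof: int = 1) -> DistributionStats:
    """Mean, standard deviation (sample by default), median and an
    integer-binned histogram of per-patient counts."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty values")
    sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    bins = np.round(arr).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    return DistributionStats(
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        histogram=dict(zip(uniq.tolist(), counts.tolist())),
        n=int(arr.size),
    )


# ---------------------------------------------------------------------------
# cohort helpers

def chronic_cohort_ids(labels: Iterable[PolypharmacyLabel], elderly_only: bool = True) -> set:
    return {
        l.patient_id
        for l in labels
        if l.chronic_polypharmacy and (l.is_elderly or not elderly_only)
    }


def monthly_series(statuses: Iterable[MonthlyStatus], year: int) -> List[int]:
    """Per calendar month, the number of patients with a qualifying month."""
    counts = [0] * 12
    for s in statuses:
        if s.qualifies:
            y, m = (int(p) for p in s.month.split("-"))
            if y == year:
                counts[m - 1] += 1
    return counts


def age_band_table(
    labels: Sequence[PolypharmacyLabel],
    patients: Mapping[str, PatientRecord],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Chronic-cohort counts and percentages per age band (65-69 .. 95+)."""
    cohort = chronic_cohort_ids(labels)
    ages = [config.study_year - patients[p].birth_year for p in cohort]
    rows = []
    for lo, hi in AGE_BANDS:
        n = sum(1 for a in ages if a >= lo and (hi is None or a <= hi))
        rows.append(
            {
                "age_band": f"{lo}+" if hi is None else f"{lo}-{hi}",
                "n": n,
                "pct": pct(n, len(cohort)) if cohort else 0.0,
            }
        )
    return pd.DataFrame(rows)


def sex_table(
    labels: Sequence[PolypharmacyLabel],
    patients: Mapping[str, PatientRecord],
) -> pd.DataFrame:
    cohort = chronic_cohort_ids(labels)
    rows = []
    for sex in (Sex.male, Sex.female, Sex.unknown):
        n = sum(1 for p in cohort if patients[p].sex == sex)
        rows.append({"sex": sex.value, "n": n, "pct": pct(n, len(cohort)) if cohort else 0.0})
    return pd.DataFrame(rows)


def regional_rates(
    labels: Sequence[PolypharmacyLabel],
    patients: Mapping[str, PatientRecord],
    denominators: Optional[ExternalDenominators] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Chronic counts and population rates per county (per 1,000
    inhabitants) and per voivodeship (per 100,000 inhabitants).

    Regions without a population entry carry counts only (rate is NaN,
    with a warning logged).
    """
    cohort = chronic_cohort_ids(labels)
    county_pop = (denominators.county_populations or {}) if denominators else {}
    voiv_pop = (denominators.voivodeship_populations or {}) if denominators else {}

    def _table(attr: str, pops: Mapping[str, int], per: int) -> pd.DataFrame:
        counts: Dict[str, int] = {code: 0 for code in pops}
        for p in cohort:
            code = getattr(patients[p], attr)
            counts[code] = counts.get(code, 0) + 1
        rows = []
        for code in sorted(counts):
            n = counts[code]
            if code in pops and pops[code] > 0:
                rate = round_half_up(per * n / pops[code], 1)
            else:
                rate = float("nan")
                if pops:
                    logger.warning("no population for region %r; rate omitted", code)
            rows.append({"region": code, "n_chronic": n, f"rate_per_{per}": rate})
        return pd.DataFrame(rows, columns=["region", "n_chronic", f"rate_per_{per}"])

    return _table("county_code", county_pop, 1_000), _table("voivodeship_code", voiv_pop, 100_000)


def top_drugs(
    claims: Iterable[DispensationRecord],
    labels: Sequence[PolypharmacyLabel],
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Ranked drug table over the chronic cohort: per substance, the share
    of patients with >= 1 dispensation and the share of all prescriptions.

    Sorted by patient share descending, ties broken by ATC code. Excluded
    ATC groups are filtered out first when a config is supplied.
    """
    config = config or AnalysisConfig()
    cohort = chronic_cohort_ids(labels)
    rules = AtcExclusionList.from_prefixes(config.excluded_atc_prefixes)
    rows = [r for r in filter_claims(claims, rules) if r.patient_id in cohort]
    if not cohort or not rows:
        return pd.DataFrame(columns=["drug_key", "n_patients", "pct_patients", "n_prescriptions", "pct_prescriptions"])
    per_drug_patients: Dict[str, set] = {}
    per_drug_rx: Dict[str, int] = {}
    for r in rows:
        key = concurrency_key(r.atc_code)
        per_drug_patients.setdefault(key, set()).add(r.patient_id)
        per_drug_rx[key] = per_drug_rx.get(key, 0) + 1
    table = pd.DataFrame(
        [
            {
                "drug_key": k,
                "n_patients": len(per_drug_patients[k]),
                "pct_patients": pct(len(per_drug_patients[k]), len(cohort)),
                "n_prescriptions": per_drug_rx[k],
                "pct_prescriptions": pct(per_drug_rx[k], len(rows)),
            }
            for k in per_drug_patients
        ]
    )
    return (
        table.sort_values(["pct_patients", "drug_key"], ascending=[False, True])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# DDD consumption

@dataclass(frozen=True)
class DddStats:
    mean_annual: float
    sd_annual: float
    mean_daily: float
    sd_daily: float
    n_ge_10_per_day: int
    share_ge_10_per_day: float
    n_ge_24_per_day: int
    share_ge_24_per_day: float
    n: int


def _days_observed(patient: PatientRecord, config: AnalysisConfig) -> int:
    import calendar as _cal

    year_days = 366 if _cal.isleap(config.study_year) else 365
    if config.ddd_daily_denominator == "full_year" or patient.death_date is None:
        return year_days
    start = date(config.study_year, 1, 1)
    if patient.death_date < start:
        return 1
    return min((patient.death_date - start).days + 1, year_days)


def ddd_stats(
    claims: Iterable[DispensationRecord],
    labels: Sequence[PolypharmacyLabel],
    patients: Mapping[str, PatientRecord],
    config: Optional[AnalysisConfig] = None,
) -> DddStats:
    """Per-patient annual and daily DDD consumption over the chronic cohort,
    with the >= 10/day and >= 24/day tail shares.

    Annual DDD = sum of packs x DDD-per-pack over included (non-excluded
    ATC) claims; the daily divisor is the days the patient was alive in the
    study year (365 when alive all year), or always the full year when
    configured so.
    """
    config = config or AnalysisConfig()
    cohort = chronic_cohort_ids(labels)
    if not cohort:
        raise ValueError("empty chronic cohort")
    rules = AtcExclusionList.from_prefixes(config.excluded_atc_prefixes)
    annual: Dict[str, float] = {p: 0.0 for p in cohort}
    for r in filter_claims(claims, rules):
        if r.patient_id in annual:
            annual[r.patient_id] += r.packs * r.ddd_per_pack
    ann = np.array([annual[p] for p in sorted(cohort)])
    daily = np.array(
        [annual[p] / _days_observed(patients[p], config) for p in sorted(cohort)]
    )
    ddof = config.sd_ddof
    n10 = int((daily >= 10).sum())
    n24 = int((daily >= 24).sum())
    return DddStats(
        mean_annual=float(ann.mean()),
        sd_annual=float(ann.std(ddof=ddof)) if ann.size > ddof else 0.0,
        mean_daily=float(daily.mean()),
        sd_daily=float(daily.std(ddof=ddof)) if daily.size > ddof else 0.0,
        n_ge_10_per_day=n10,
        share_ge_10_per_day=pct(n10, len(cohort)),
        n_ge_24_per_day=n24,
        share_ge_24_per_day=pct(n24, len(cohort)),
        n=len(cohort),
    )


def contact_stats(
    claims: Iterable[DispensationRecord],
    labels: Sequence[PolypharmacyLabel],
    config: Optional[AnalysisConfig] = None,
) -> Dict[str, DistributionStats]:
    """Distributions of distinct prescribers, encounters and providers per
    chronic-cohort patient (from the claims' identifier columns)."""
    config = config or AnalysisConfig()
    cohort = chronic_cohort_ids(labels)
    if not cohort:
        raise ValueError("empty chronic cohort")
    rules = AtcExclusionList.from_prefixes(config.excluded_atc_prefixes)
    sets: Dict[str, Dict[str, set]] = {
        "prescribers": {p: set() for p in cohort},
        "encounters": {p: set() for p in cohort},
        "providers": {p: set() for p in cohort},
    }
    for r in filter_claims(claims, rules):
        if r.patient_id in cohort:
            if r.prescriber_id:
                sets["prescribers"][r.patient_id].add(r.prescriber_id)
            if r.encounter_id:
                sets["encounters"][r.patient_id].add(r.encounter_id)
            if r.provider_id:
                sets["providers"][r.patient_id].add(r.provider_id)
    ddof = config.sd_ddof
    return {
        name: distribution_stats([len(s) for s in per.values()], ddof=ddof)
        for name, per in sets.items()
    }


# ---------------------------------------------------------------------------
# healthcare utilization

@dataclass
class UtilizationSummary:
    service_table: pd.DataFrame
    outpatient_diagnoses: pd.DataFrame
    hospital_diagnoses: pd.DataFrame
    hospitalisation_rate_mean: float
    hospitalisation_rate_sd: float
    n_hospitalisations: int
    n_cohort: int


def utilization_summary(
    utilization: Iterable[UtilizationRecord],
    labels: Sequence[PolypharmacyLabel],
    config: Optional[AnalysisConfig] = None,
) -> UtilizationSummary:
    """Service-type and principal-diagnosis tables for the chronic cohort.

    The hospitalisation-diagnosis table carries both denominators — share
    of hospitalisations and share of cohort patients. The hospitalisation
    rate is hospitalisation events per chronic patient (zeros included),
    mean +/- sd.
    """
    config = config or AnalysisConfig()
    cohort = chronic_cohort_ids(labels)
    if not cohort:
        raise ValueError("empty chronic cohort")
    util = [u for u in utilization if u.patient_id in cohort]

    svc_patients: Dict[str, set] = {s: set() for s in SERVICE_TYPES}
    out_dx_patients: Dict[str, set] = {}
    hosp_dx_events: Dict[str, int] = {}
    hosp_per_patient: Dict[str, int] = {p: 0 for p in cohort}
    for u in util:
        svc_patients[u.service_type].add(u.patient_id)
        if u.is_hospitalisation:
            hosp_per_patient[u.patient_id] += 1
            if u.icd10_code:
                hosp_dx_events[u.icd10_code] = hosp_dx_events.get(u.icd10_code, 0) + 1
        elif u.icd10_code:
            out_dx_patients.setdefault(u.icd10_code, set()).add(u.patient_id)

    n = len(cohort)
    service_table = pd.DataFrame(
        [
            {"service_type": s, "n_patients": len(svc_patients[s]), "pct_of_cohort": pct(len(svc_patients[s]), n)}
            for s in SERVICE_TYPES
        ]
    )
    outpatient = pd.DataFrame(
        [
            {"icd10": code, "n_patients": len(pats), "pct_of_cohort": pct(len(pats), n)}
            for code, pats in out_dx_patients.items()
        ]
    )
    if len(outpatient):
        outpatient = outpatient.sort_values(
            ["n_patients", "icd10"], ascending=[False, True]
        ).reset_index(drop=True)
    n_hosp = sum(hosp_per_patient.values())
    hospital = pd.DataFrame(
        [
            {
                "icd10": code,
                "n_hospitalisations": cnt,
                "pct_of_hospitalisations": pct(cnt, n_hosp) if n_hosp else 0.0,
                "pct_of_cohort": pct(cnt, n),
            }
            for code, cnt in hosp_dx_events.items()
        ]
    )
    if len(hospital):
        hospital = hospital.sort_values(
            ["n_hospitalisations", "icd10"], ascending=[False, True]
        ).reset_index(drop=True)
    rates = np.array([hosp_per_patient[p] for p in sorted(cohort)], dtype=float)
    ddof = config.sd_ddof
    return UtilizationSummary(
        service_table=service_table,
        outpatient_diagnoses=outpatient,
        hospital_diagnoses=hospital,
        hospitalisation_rate_mean=float(rates.mean()),
        hospitalisation_rate_sd=float(rates.std(ddof=ddof)) if rates.size > ddof else 0.0,
        n_hospitalisations=int(n_hosp),
        n_cohort=n,
    )


# ---------------------------------------------------------------------------
# top-level summary object

@dataclass
class CohortSummary:
    """Aggregate descriptive layer for one analysed cohort.

    Counts are stored alongside the denominators used, so every percentage
    can be re-derived; ``None`` marks a section whose inputs were absent
    (e.g. no utilization table supplied), as opposed to a true zero.
    """

    config: AnalysisConfig
    n_registry: int
    n_elderly_registry: int
    n_basic_all_ages: int
    n_basic_elderly: int
    n_chronic_elderly: int
    n_whole_year_elderly: int
    pct_elderly_of_polypharmacy: float
    pct_elderly_polypharmacy_of_elderly_pop: float
    pct_chronic_of_total_pop: float
    pct_chronic_of_elderly_pop: float
    pct_whole_year_of_chronic: float
    age_bands: pd.DataFrame
    sexes: pd.DataFrame
    monthly: List[int]
    county_rates: pd.DataFrame
    voivodeship_rates: pd.DataFrame
    drugs: pd.DataFrame
    ddd: Optional[DddStats]
    contacts: Optional[Dict[str, DistributionStats]]
    utilization: Optional[UtilizationSummary]

    def tables(self) -> Dict[str, pd.DataFrame]:
        """Writable delimited-text views of every summary table."""
        out: Dict[str, pd.DataFrame] = {
            "prevalence": pd.DataFrame(
                [
                    {"quantity": "n_basic_all_ages", "value": self.n_basic_all_ages},
                    {"quantity": "n_basic_elderly", "value": self.n_basic_elderly},
                    {"quantity": "n_chronic_elderly", "value": self.n_chronic_elderly},
                    {"quantity": "n_whole_year_elderly", "value": self.n_whole_year_elderly},
                    {"quantity": "pct_elderly_of_polypharmacy", "value": self.pct_elderly_of_polypharmacy},
                    {"quantity": "pct_elderly_polypharmacy_of_elderly_pop", "value": self.pct_elderly_polypharmacy_of_elderly_pop},
                    {"quantity": "pct_chronic_of_total_pop", "value": self.pct_chronic_of_total_pop},
                    {"quantity": "pct_chronic_of_elderly_pop", "value": self.pct_chronic_of_elderly_pop},
                    {"quantity": "pct_whole_year_of_chronic", "value": self.pct_whole_year_of_chronic},
                ]
            ),
            "demographics_age": self.age_bands,
            "demographics_sex": self.sexes,
            "monthly_series": pd.DataFrame(
                {"month": [f"{m:02d}" for m in range(1, 13)], "n_qualifying": self.monthly}
            ),
            "regional_rates_county": self.county_rates,
            "regional_rates_voivodeship": self.voivodeship_rates,
            "top_drugs": self.drugs,
        }
        if self.utilization is not None:
            out["service_utilization"] = self.utilization.service_table
            out["outpatient_diagnoses"] = self.utilization.outpatient_diagnoses
            out["hospitalisation_diagnoses"] = self.utilization.hospital_diagnoses
        return out

    def summary(self) -> str:
        """Human-readable digest of the headline numbers."""
        lines = [
            "Cohort summary",
            "==============",
            f"registry patients:              {self.n_registry}",
            f"  of whom elderly:              {self.n_elderly_registry}",
            f"basic polypharmacy (all ages):  {self.n_basic_all_ages}",
            f"basic polypharmacy (elderly):   {self.n_basic_elderly}"
            f"  ({self.pct_elderly_of_polypharmacy}% of polypharmacy group,"
            f" {self.pct_elderly_polypharmacy_of_elderly_pop}% of elderly)",
            f"chronic polypharmacy (elderly): {self.n_chronic_elderly}"
            f"  ({self.pct_chronic_of_elderly_pop}% of elderly)",
            f"  whole-year persistent:        {self.n_whole_year_elderly}"
            f"  ({self.pct_whole_year_of_chronic}% of chronic)",
            "monthly qualifying counts:      " + " ".join(str(c) for c in self.monthly),
        ]
        if self.ddd is not None:
            lines.append(
                f"DDD per patient: {self.ddd.mean_annual:.0f}±{self.ddd.sd_annual:.0f}/year, "
                f"{self.ddd.mean_daily:.1f}±{self.ddd.sd_daily:.2f}/day "
                f"(>=10/day: {self.ddd.share_ge_10_per_day}%, >=24/day: {self.ddd.share_ge_24_per_day}%)"
            )
        if self.contacts is not None:
            c = self.contacts
            lines.append(
                f"prescribers per patient: median {c['prescribers'].median:.0f} "
                f"(mean {c['prescribers'].mean:.1f}±{c['prescribers'].sd:.2f}); "
                f"encounters {c['encounters'].mean:.1f}±{c['encounters'].sd:.2f}; "
                f"providers {c['providers'].mean:.1f}±{c['providers'].sd:.2f}"
            )
        if self.utilization is not None:
            u = self.utilization
            lines.append(
                f"hospitalisations: {u.n_hospitalisations} "
                f"(rate {u.hospitalisation_rate_mean:.2f}±{u.hospitalisation_rate_sd:.2f} per patient)"
            )
        return "\n".join(lines)


def build_summary(
    labels: Sequence[PolypharmacyLabel],
    statuses: Sequence[MonthlyStatus],
    claims: Iterable[DispensationRecord],
    patients: Mapping[str, PatientRecord],
    config: Optional[AnalysisConfig] = None,
    denominators: Optional[ExternalDenominators] = None,
    utilization: Optional[Iterable[UtilizationRecord]] = None,
) -> CohortSummary:
    """Assemble the full descriptive layer from pipeline outputs.

    When no external population denominators are supplied, the registry
    itself is the population (appropriate for synthetic cohorts).
    """
    config = config or AnalysisConfig()
    claims = list(claims)
    n_registry = len(labels)
    n_elderly = sum(1 for l in labels if l.is_elderly)
    if denominators is None:
        denominators = ExternalDenominators(
            national_population=max(n_registry, 1),
            elderly_population=max(n_elderly, 1),
        )
    basic_all = sum(1 for l in labels if l.basic_polypharmacy)
    basic_eld = sum(1 for l in labels if l.basic_polypharmacy and l.is_elderly)
    chronic_eld = sum(1 for l in labels if l.chronic_polypharmacy and l.is_elderly)
    whole_eld = sum(1 for l in labels if l.whole_year and l.is_elderly)

    elderly_ids = {l.patient_id for l in labels if l.is_elderly}
    elderly_statuses = [s for s in statuses if s.patient_id in elderly_ids]

    county, voiv = regional_rates(labels, patients, denominators)
    cohort = chronic_cohort_ids(labels)
    ddd = ddd_stats(claims, labels, patients, config) if cohort else None
    contacts = contact_stats(claims, labels, config) if cohort else None
    util = (
        utilization_summary(utilization, labels, config)
        if utilization is not None and cohort
        else None
    )
    return CohortSummary(
        config=config,
        n_registry=n_registry,
        n_elderly_registry=n_elderly,
        n_basic_all_ages=basic_all,
        n_basic_elderly=basic_eld,
        n_chronic_elderly=chronic_eld,
        n_whole_year_elderly=whole_eld,
        pct_elderly_of_polypharmacy=pct(basic_eld, basic_all) if basic_all else 0.0,
        pct_elderly_polypharmacy_of_elderly_pop=pct(basic_eld, denominators.elderly_population),
        pct_chronic_of_total_pop=pct(chronic_eld, denominators.national_population),
        pct_chronic_of_elderly_pop=pct(chronic_eld, denominators.elderly_population),
        pct_whole_year_of_chronic=pct(whole_eld, chronic_eld) if chronic_eld else 0.0,
        age_bands=age_band_table(labels, patients, config),
        sexes=sex_table(labels, patients),
        monthly=monthly_series(elderly_statuses, config.study_year),
        county_rates=county,
        voivodeship_rates=voiv,
        drugs=top_drugs(claims, labels, config),
        ddd=ddd,
        contacts=contacts,
        utilization=util,
    )


def plot_monthly_series(series: Sequence[int], path, year: int = 2018) -> None:
    """Optional bar chart of the monthly qualifying-patient counts
    (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(1, 13), list(series), color="#446e9b")
    ax.set_xticks(range(1, 13))
    ax.set_xlabel(f"month of {year}")
    ax.set_ylabel("patients on >=5 drugs for >=80% of days")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
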