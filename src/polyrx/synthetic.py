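"""Synthetic payer-database emulator with designed ground truth.

Generates the three input tables — dispensation claims, patient registry,
healthcare utilization — for a cohort of elderly patients, together with a
ground-truth table saying which patients were *designed* to be chronic
polypharmacy cases, basic-only cases, or neither. The pipeline can then be
tested end-to-end with no external data: recovery of the designed labels
is the headline validation.

Design of the refill process
----------------------------
Chronic-designed patients receive, for every regimen drug, one 30-day
supply at the start of each month of their designed qualifying window
(start day jittered by at most ``refill_jitter_days``). With jitter 0 this
guarantees >= 80% day-level coverage of every designed month and makes the
classifier's sensitivity/specificity exactly measurable. Basic-only
patients get >= ``min_drugs`` distinct drugs inside a 183-day window but
staggered so no five are ever concurrent; "neither" patients get at most
four distinct drugs. Excluded-ATC noise rows (antibiotics, laxatives,
dermatologicals, ...) are added to every stratum and must never change a
label. Refill gaps (``gap_probability``) apply to non-chronic designs
only.

Chronic regimens are drawn by independent Bernoulli inclusion at the
seeded per-drug patient shares, topped up from a disjoint filler pool to
the size target drawn from ``regimen_size_distribution`` — so the seeded
shares are recovered unbiasedly by the top-drug summary while regimen
sizes still follow the configured distribution.

Designed qualifying windows start later in the year more often than
earlier (weights proportional to the start month), emulating the seasonal
accumulation seen in real dispensation data, where January — with no
carryover from the previous year — has the fewest qualifying patients and
December the most.

About 4% of the cohort dies in-year (sampled in October..December, never
from the whole-year stratum, with all dispensations placed before death),
exercising the mid-year censoring path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .records import (
    DispensationRecord,
    PatientRecord,
    SERVICE_TYPES,
    Sex,
    UtilizationRecord,
)

# --------------------------------------------------------------------------
# default configuration data (editable, not code)

#: (age_lo, age_hi, weight) — chronic-cohort age structure.
DEFAULT_AGE_BANDS: Tuple[Tuple[int, int, float], ...] = (
    (65, 69, 0.2095), (70, 74, 0.2389), (75, 79, 0.2047),
    (80, 84, 0.1792), (85, 89, 0.0976), (90, 94, 0.0271), (95, 99, 0.0035),
)

#: ATC level-5 code -> per-patient share (%) among chronic patients.
DEFAULT_DRUG_SHARES: Dict[str, float] = {
    "A10BA02": 50.3,  # metformin
    "C10AA05": 46.7,  # atorvastatin
    "A02BC02": 38.0,  # pantoprazole
    "C09AA05": 35.3,  # ramipril
    "C08CA01": 33.2,  # amlodipine
    "C03CA01": 27.2,  # furosemide
    "M04AA01": 25.8,  # allopurinol
    "C10AA07": 25.3,  # rosuvastatin
    "G04CA02": 24.7,  # tamsulosin
    "C07AB12": 23.9,  # nebivolol
    "N02AJ13": 23.3,  # tramadol + paracetamol (one combination = one drug)
    "C03BA11": 23.3,  # indapamide
    "A12BA01": 21.9,  # potassium chloride
    "G04CB01": 21.1,  # finasteride
    "C03DA01": 18.5,  # spironolactone
    "A02BC01": 18.1,  # omeprazole
    "H03AA01": 16.7,  # levothyroxine
    "C02CA04": 16.5,  # doxazosin
    "A10BB09": 15.9,  # gliclazide
    "A10BB12": 14.4,  # glimepiride
}

#: Disjoint filler pool used only to top regimens up to their size target.
DEFAULT_FILLER_DRUGS: Tuple[str, ...] = (
    "B01AC06", "C07AB07", "C09CA01", "C09AA02", "C01DA14", "N05BA04",
    "N06AB05", "N02BE01", "A02BA02", "C01AA05", "C03AA03", "C09BA02",
    "B01AA03", "C08CA05", "N05CF02", "M01AE01", "R03AK06", "A11CC05",
    "N03AX16", "C10AB05", "A07EC02", "G03CA03", "M05BA04", "N06AX11",
    "H02AB06", "L04AX03", "R03BB04", "C01BD01", "N04BA02", "S01ED51",
)

#: Excluded-ATC noise codes (short-term therapies) sprinkled into claims.
DEFAULT_NOISE_CODES: Tuple[str, ...] = (
    "J01CA04", "J01FA10", "A06AB02", "A06AD11", "D07AC01", "D01AC02",
    "A01AB09", "V03AB16", "J02AC01", "J05AB01", "J06BA02", "J07AL02",
    "P03AC04",
)

#: service type -> presence probability among chronic patients
#: (count-consistent shares; non-chronic strata are scaled down).
DEFAULT_SERVICE_PRESENCE: Dict[str, float] = {
    "Primary healthcare": 0.983,
    "Outpatient specialist services": 0.860,
    "Hospital treatment": 0.514,
    "Medical rehabilitation": 0.222,
    "Emergency medical services": 0.213,
    "Psychiatric care and addiction treatment": 0.071,
    "Services contracted separately": 0.027,
    "Palliative and hospice care": 0.016,
    "Nursing and care services": 0.014,
    "Pilot programs": 0.005,
}

#: ICD-10 -> presence probability (%) of an outpatient principal diagnosis.
DEFAULT_OUTPATIENT_DX: Dict[str, float] = {
    "Z76.0": 57.2, "I10": 51.0, "E11": 35.5, "N40": 21.7, "Z76.8": 21.5,
    "I25": 20.4, "Z76.3": 14.1, "I50": 13.8, "I48": 12.5, "Z03": 12.4,
    "M47": 12.3, "J44": 11.7, "J06.9": 11.5, "M15": 10.4, "I11": 10.1,
    "J45": 9.6, "Z71": 9.1, "M54.1": 9.0, "Z00": 8.6, "J20": 8.4,
}

#: ICD-10 -> sampling weight for hospitalisation principal diagnoses.
DEFAULT_HOSPITAL_DX: Dict[str, float] = {
    "I50.9": 3.8, "H26.2": 2.9, "I50.0": 2.8, "I48": 1.9, "H25.8": 1.7,
    "I25.0": 1.6, "I50.1": 1.1, "I10": 1.1, "Z51.1": 1.1, "I21.4": 1.1,
    "I70.2": 0.9, "I20.0": 0.8, "K80.2": 2.0, "J18.9": 2.0, "N39.0": 1.5,
    "C61": 1.5, "E86": 1.2, "S72.0": 1.0,
}

#: voivodeship -> (weight, counties) for the synthetic mini-geography.
DEFAULT_REGIONS: Dict[str, Tuple[float, Tuple[str, ...]]] = {
    "10": (0.25, ("1061", "1062", "1063")),   # lodzkie
    "14": (0.45, ("1465", "1401", "1402")),   # mazowieckie
    "24": (0.30, ("2469", "2475", "2401")),   # slaskie
}


@dataclass(frozen=True)
class GroundTruth:
    """Designed label of one synthetic patient (the recovery target)."""

    patient_id: str
    designed_label: str  # chronic | basic_only | neither
    designed_regimen: Tuple[str, ...]
    designed_qualifying_months: Tuple[int, ...]


@dataclass
class GeneratorConfig:
    n_patients: int = 1000
    seed: int = 0
    study_year: int = 2018
    min_drugs: int = 5
    age_distribution: Tuple[Tuple[int, int, float], ...] = DEFAULT_AGE_BANDS
    sex_male_fraction: float = 0.493
    region_weights: Mapping[str, Tuple[float, Tuple[str, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    designed_chronic_fraction: float = 0.19
    designed_basic_only_fraction: float = 0.24
    designed_whole_year_fraction: float = 0.686
    regimen_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {5: 0.12, 6: 0.14, 7: 0.16, 8: 0.18, 9: 0.14, 10: 0.10, 11: 0.08, 12: 0.08}
    )
    drug_frequency_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_SHARES)
    )
    filler_drug_pool: Tuple[str, ...] = DEFAULT_FILLER_DRUGS
    excluded_noise_codes: Tuple[str, ...] = DEFAULT_NOISE_CODES
    refill_jitter_days: int = 2
    gap_probability: float = 0.08
    pack_ddd_menu: Tuple[float, ...] = (28.0, 30.0, 56.0, 60.0, 90.0)
    prescriber_pool: int = 400
    provider_pool: int = 150
    hospitalisation_rate_mean: float = 1.03
    service_presence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SERVICE_PRESENCE)
    )
    outpatient_diagnosis_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTPATIENT_DX)
    )
    hospital_diagnosis_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOSPITAL_DX)
    )
    death_fraction: float = 0.039

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        fr = self.designed_chronic_fraction + self.designed_basic_only_fraction
        if not (0 <= self.designed_chronic_fraction <= 1 and 0 <= self.designed_basic_only_fraction <= 1 and fr <= 1):
            raise ValueError("designed fractions must be in [0,1] and sum to <= 1")
        if self.refill_jitter_days < 0:
            raise ValueError("refill_jitter_days must be >= 0")
        if not 0 <= self.gap_probability <= 1:
            raise ValueError("gap_probability must be in [0,1]")
        if any(w < 0 for w in self.drug_frequency_table.values()):
            raise ValueError("drug weights must be nonnegative")
        if self.designed_chronic_fraction > 0:
            sizes = [s for s, w in self.regimen_size_distribution.items() if w > 0]
            if not sizes or max(sizes) < self.min_drugs:
                raise ValueError(
                    "infeasible config: regimen_size_distribution support below min_drugs "
                    "with a positive chronic fraction"
                )
            if len(self.drug_frequency_table) + len(self.filler_drug_pool) < self.min_drugs:
                raise ValueError("infeasible config: fewer candidate drugs than min_drugs")


@dataclass
class SyntheticCohort:
    patients: List[PatientRecord]
    claims: List[DispensationRecord]
    utilization: List[UtilizationRecord]
    ground_truth: List[GroundTruth]

    def registry(self) -> Dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def truth_by_id(self) -> Dict[str, GroundTruth]:
        return {g.patient_id: g for g in self.ground_truth}


def _weighted_choice(rng: np.random.Generator, items: Sequence, weights: Sequence[float]):
    w = np.asarray(weights, dtype=float)
    return items[int(rng.choice(len(items), p=w / w.sum()))]


def _month_day(year: int, month: int, day: int) -> date:
    import calendar

    return date(year, month, min(day, calendar.monthrange(year, month)[1]))


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Generate the full synthetic cohort. Deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    year = config.study_year
    n = config.n_patients

    n_chronic = int(round(config.designed_chronic_fraction * n))
    n_basic = int(round(config.designed_basic_only_fraction * n))
    n_basic = min(n_basic, n - n_chronic)
    strata = ["chronic"] * n_chronic + ["basic_only"] * n_basic
    strata += ["neither"] * (n - len(strata))
    strata = [strata[i] for i in rng.permutation(n)]

    n_whole = int(round(config.designed_whole_year_fraction * n_chronic))
    # whole-year flags assigned to the first n_whole chronic patients in id order
    whole_flags: List[bool] = []
    seen_chronic = 0
    for s in strata:
        if s == "chronic":
            whole_flags.append(seen_chronic < n_whole)
            seen_chronic += 1
        else:
            whole_flags.append(False)

    # deaths: never whole-year chronic; dates in Oct..Dec
    death_candidates = [i for i in range(n) if not whole_flags[i]]
    n_deaths = min(int(round(config.death_fraction * n)), len(death_candidates))
    dead = set(
        rng.choice(death_candidates, size=n_deaths, replace=False).tolist()
        if n_deaths
        else []
    )

    table_drugs = sorted(config.drug_frequency_table)
    table_p = np.array([config.drug_frequency_table[d] / 100.0 for d in table_drugs])
    sizes = sorted(config.regimen_size_distribution)
    size_w = np.array([config.regimen_size_distribution[s] for s in sizes], dtype=float)
    size_w = size_w / size_w.sum()

    voivs = sorted(config.region_weights)
    voiv_w = [config.region_weights[v][0] for v in voivs]

    patients: List[PatientRecord] = []
    claims: List[DispensationRecord] = []
    utilization: List[UtilizationRecord] = []
    truth: List[GroundTruth] = []

    width = max(6, len(str(n)))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        stratum = strata[i]

        # --- demographics -------------------------------------------------
        bands = config.age_distribution
        lo, hi, _ = _weighted_choice(rng, list(bands), [b[2] for b in bands])
        age = int(rng.integers(lo, hi + 1))
        sex = Sex.male if rng.random() < config.sex_male_fraction else Sex.female
        voiv = _weighted_choice(rng, voivs, voiv_w)
        county = str(rng.choice(list(config.region_weights[voiv][1])))
        death: Optional[date] = None
        if i in dead:
            death = date(year, 10, 1) + timedelta(days=int(rng.integers(0, 90)))
        patients.append(
            PatientRecord(
                patient_id=pid,
                birth_year=year - age,
                sex=sex,
                county_code=county,
                voivodeship_code=voiv,
                death_date=death,
            )
        )

        # --- contact identifier pools ------------------------------------
        n_presc = max(1, min(config.prescriber_pool, 1 + int(rng.poisson(3.5))))
        presc_ids = rng.choice(config.prescriber_pool, size=n_presc, replace=False)
        n_enc = max(1, 1 + int(rng.poisson(13.7)))
        enc_presc = rng.integers(0, n_presc, size=n_enc)

        def emit(day: date, atc: str, packs: int, ddd: float) -> None:
            e = int(rng.integers(0, n_enc))
            pr = int(presc_ids[enc_presc[e]])
            claims.append(
                DispensationRecord(
                    patient_id=pid,
                    dispense_date=day,
                    atc_code=atc,
                    packs=packs,
                    ddd_per_pack=ddd,
                    prescriber_id=f"DR{pr:05d}",
                    provider_id=f"HC{pr % config.provider_pool:04d}",
                    encounter_id=f"{pid}-E{e + 1:03d}",
                )
            )

        # --- designed dispensation pattern --------------------------------
        regimen: Tuple[str, ...] = ()
        months: Tuple[int, ...] = ()
        if stratum == "chronic":
            if whole_flags[i]:
                start, length = 1, 12
            elif i in dead:
                start, length = 1, 6
            else:
                length = int(rng.integers(6, 12))
                feasible = list(range(1, 13 - length + 1))
                start = _weighted_choice(rng, feasible, [float(k) for k in feasible])
            months = tuple(range(start, start + length))
            include = rng.random(len(table_drugs)) < table_p
            drugs = [d for d, inc in zip(table_drugs, include) if inc]
            target = int(_weighted_choice(rng, sizes, size_w))
            target = max(target, config.min_drugs)
            if len(drugs) < target:
                extra = rng.choice(
                    len(config.filler_drug_pool),
                    size=min(target - len(drugs), len(config.filler_drug_pool)),
                    replace=False,
                )
                drugs += [config.filler_drug_pool[int(k)] for k in sorted(extra)]
            regimen = tuple(sorted(drugs))
            for m in months:
                for drug in regimen:
                    day = 1 + int(rng.integers(0, config.refill_jitter_days + 1))
                    emit(_month_day(year, m, day), drug, 1, 30.0)
        elif stratum == "basic_only":
            m_drugs = int(rng.integers(config.min_drugs, config.min_drugs + 3))
            order = rng.permutation(len(table_drugs))[:m_drugs]
            drugs = [table_drugs[int(k)] for k in order]
            regimen = tuple(sorted(drugs))
            first_off = int(rng.integers(0, 20 if i in dead else 90))
            for j, drug in enumerate(drugs):
                off = first_off + 33 * j + int(rng.integers(0, config.refill_jitter_days + 1))
                d0 = date(year, 1, 1) + timedelta(days=off)
                emit(d0, drug, 1, 30.0)
                if rng.random() >= config.gap_probability:
                    d1 = d0 + timedelta(days=30)
                    if d1.year == year and (death is None or d1 <= death):
                        emit(d1, drug, 1, 30.0)
        else:  # neither
            k = int(rng.integers(1, config.min_drugs))  # <= min_drugs - 1 distinct
            order = rng.permutation(len(table_drugs))[:k]
            drugs = [table_drugs[int(j)] for j in order]
            regimen = tuple(sorted(drugs))
            last_day = 243 if i in dead else 273  # Aug/Sep cut-off
            for drug in drugs:
                for _ in range(int(rng.integers(1, 4))):
                    if rng.random() < config.gap_probability:
                        continue
                    off = int(rng.integers(0, last_day))
                    ddd = float(rng.choice(list(config.pack_ddd_menu)))
                    emit(date(year, 1, 1) + timedelta(days=off), drug, int(rng.integers(1, 3)), ddd)

        # excluded-ATC noise rows in every stratum
        for _ in range(int(rng.integers(1, 4))):
            code = str(rng.choice(list(config.excluded_noise_codes)))
            off = int(rng.integers(0, 243 if i in dead else 365))
            emit(date(year, 1, 1) + timedelta(days=off), code, 1, float(rng.choice(list(config.pack_ddd_menu))))

        truth.append(
            GroundTruth(
                patient_id=pid,
                designed_label=stratum,
                designed_regimen=regimen,
                designed_qualifying_months=months,
            )
        )

        # --- healthcare utilization ---------------------------------------
        scale = 1.0 if stratum == "chronic" else 0.5
        out_dx = sorted(config.outpatient_diagnosis_weights)
        out_p = np.array([config.outpatient_diagnosis_weights[c] / 100.0 for c in out_dx])
        hosp_dx = sorted(config.hospital_diagnosis_weights)
        hosp_w = np.array([config.hospital_diagnosis_weights[c] for c in hosp_dx])
        hosp_w = hosp_w / hosp_w.sum()
        max_off = (death - date(year, 1, 1)).days if death else 364

        def udate() -> date:
            return date(year, 1, 1) + timedelta(days=int(rng.integers(0, max_off + 1)))

        present_dx = [c for c, r in zip(out_dx, rng.random(len(out_dx)) < out_p * scale) if r]
        for svc, p in config.service_presence.items():
            if svc == "Hospital treatment":
                continue
            if rng.random() < p * scale:
                n_events = 1 + int(rng.poisson(11.8)) if svc == "Primary healthcare" else (
                    1 + int(rng.poisson(6.6)) if svc == "Outpatient specialist services" else 1
                )
                for _ in range(n_events):
                    dx = str(rng.choice(present_dx)) if present_dx else "Z00"
                    utilization.append(
                        UtilizationRecord(pid, svc, udate(), dx, is_hospitalisation=False)
                    )
        if rng.random() < config.service_presence.get("Hospital treatment", 0.5) * scale:
            lam = config.hospitalisation_rate_mean / max(
                config.service_presence.get("Hospital treatment", 0.5), 1e-9
            )
            n_hosp = 1 + int(rng.poisson(max(lam - 1.0, 0.0)))
            for _ in range(n_hosp):
                dx = str(rng.choice(hosp_dx, p=hosp_w))
                utilization.append(
                    UtilizationRecord(pid, "Hospital treatment", udate(), dx, is_hospitalisation=True)
                )

    return SyntheticCohort(patients, claims, utilization, truth)


def perturb_adherence(
    claims: Sequence[DispensationRecord],
    ground_truth: Sequence[GroundTruth],
    drop_fraction: float,
    seed: int,
) -> List[DispensationRecord]:
    """Delete a fraction of chronic-designed patients' regimen refills.

    Used to trace the classifier's sensitivity as adherence degrades.
    Exactly ``floor(drop_fraction x eligible)`` rows are removed, chosen
    uniformly without replacement; order of the survivors is preserved.
    """
    if not 0 <= drop_fraction <= 1:
        raise ValueError("drop_fraction must be in [0,1]")
    truth = {g.patient_id: g for g in ground_truth}
    eligible = [
        i
        for i, r in enumerate(claims)
        if (g := truth.get(r.patient_id)) is not None
        and g.designed_label == "chronic"
        and r.atc_code in g.designed_regimen
    ]
    n_drop = math.floor(drop_fraction * len(eligible))
    rng = np.random.default_rng(seed)
    dropped = set(rng.choice(eligible, size=n_drop, replace=False).tolist()) if n_drop else set()
    return [r for i, r in enumerate(claims) if i not in dropped]


def region_populations(
    cohort: SyntheticCohort, elderly_share: float = 0.02
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Synthetic population denominators for the mini-geography: each
    region's population is its patient count scaled up as if the cohort
    were ``elderly_share`` of the general population."""
    county: Dict[str, int] = {}
    voiv: Dict[str, int] = {}
    for p in cohort.patients:
        county[p.county_code] = county.get(p.county_code, 0) + 1
        voiv[p.voivodeship_code] = voiv.get(p.voivodeship_code, 0) + 1
    scale = 1.0 / elderly_share
    return (
        {k: int(round(v * scale)) for k, v in county.items()},
        {k: int(round(v * scale)) for k, v in voiv.items()},
    )
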