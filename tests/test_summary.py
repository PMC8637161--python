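"""Descriptive-summary layer: percentages, distributions, tables."""

import calendar
from datetime import date, timedelta

import numpy as np
import pytest

from polyrx import AnalysisConfig, ExternalDenominators
from polyrx.classifier import classify_cohort
from polyrx.records import (
    DispensationRecord,
    MonthlyStatus,
    PatientRecord,
    PolypharmacyLabel,
    Sex,
    UtilizationRecord,
)
from polyrx.summary import (
    build_summary,
    contact_stats,
    ddd_stats,
    distribution_stats,
    monthly_series,
    pct,
    regional_rates,
    round_half_up,
    top_drugs,
    utilization_summary,
    verify_ratio,
)


# ------------------------------------------------------------------ pct ----

@pytest.mark.parametrize(
    "num,den,expected",
    [
        (2_899_000, 4_507_000, 64.3),
        (0, 554_085, 0.0),
        (554_085, 38_411_148, 1.4),
        (1, 3, 33.3),
        (1, 8, 12.5),
    ],
)
def test_pct(num, den, expected):
    assert pct(num, den) == expected


def test_pct_zero_denominator_is_error():
    with pytest.raises(ValueError):
        pct(1, 0)


def test_rounding_is_half_up_not_bankers():
    assert round_half_up(0.05, 1) == 0.1
    assert round_half_up(2.25, 1) == 2.3
    assert round_half_up(12.849, 1) == 12.8


def test_verify_ratio_flags_inconsistent_printed_cells():
    assert verify_ratio(272_922, 554_085, 49.3)       # consistent
    assert not verify_ratio(544_934, 554_085, 98.7)   # recomputes to 98.3


# -------------------------------------------------------- distributions ----

def test_distribution_stats_degenerate():
    s = distribution_stats([4, 4, 4])
    assert (s.mean, s.sd, s.median) == (4.0, 0.0, 4.0)
    assert s.histogram == {4: 3}


def test_distribution_stats_sample_sd():
    s = distribution_stats([1, 2, 3, 4, 5])
    assert s.mean == 3.0 and s.median == 3.0
    assert s.sd == pytest.approx(1.5811, abs=1e-4)


def test_distribution_stats_empty_is_error():
    with pytest.raises(ValueError):
        distribution_stats([])


# -------------------------------------------------------------- fixtures ---

def _label(pid, chronic=True, elderly=True, whole=False, basic=True):
    return PolypharmacyLabel(
        patient_id=pid, is_elderly=elderly, basic_polypharmacy=basic,
        chronic_polypharmacy=chronic,
        longest_qualifying_run_months=12 if whole else (6 if chronic else 0),
        whole_year=whole and chronic, distinct_drugs_6m=5 if basic else 2,
    )


def _patient(pid, age=75, county="1061", voiv="10", death=None, sex=Sex.female):
    return PatientRecord(pid, 2018 - age, sex, county, voiv, death)


def _status(pid, month, qualifies):
    dim = calendar.monthrange(2018, month)[1]
    d = dim if qualifies else 0
    return MonthlyStatus(pid, f"2018-{month:02d}", dim, d, d / dim, qualifies)


# --------------------------------------------------------- monthly series --

def test_monthly_series_constant_cohort():
    statuses = [_status(f"P{i}", m, True) for i in range(10) for m in range(1, 13)]
    assert monthly_series(statuses, 2018) == [10] * 12


def test_monthly_series_single_june_qualifier():
    statuses = [_status("P1", m, m == 6) for m in range(1, 13)]
    assert monthly_series(statuses, 2018) == [0] * 5 + [1] + [0] * 6


def test_monthly_series_matches_bruteforce_recount():
    rng = np.random.default_rng(2)
    statuses = [
        _status(f"P{i}", m, bool(rng.random() < 0.4))
        for i in range(50)
        for m in range(1, 13)
    ]
    got = monthly_series(statuses, 2018)
    for m in range(1, 13):
        brute = sum(1 for s in statuses if s.month == f"2018-{m:02d}" and s.qualifies)
        assert got[m - 1] == brute


# -------------------------------------------------------- regional rates ---

def test_regional_rates_printed_scale():
    labels = [_label(f"P{i}") for i in range(23)]
    patients = {l.patient_id: _patient(l.patient_id, county="4001", voiv="40") for l in labels}
    den = ExternalDenominators(
        county_populations={"4001": 1000}, voivodeship_populations={"40": 100_000}
    )
    county, voiv = regional_rates(labels, patients, den)
    assert county.loc[0, "rate_per_1000"] == 23.0
    assert voiv.loc[0, "rate_per_100000"] == 23.0


def test_regional_rates_zero_and_missing_population():
    labels = [_label("P1")]
    patients = {"P1": _patient("P1", county="4001", voiv="40")}
    den = ExternalDenominators(
        county_populations={"4001": 500, "4002": 800}, voivodeship_populations={}
    )
    county, voiv = regional_rates(labels, patients, den)
    by_region = county.set_index("region")
    assert by_region.loc["4002", "n_chronic"] == 0 and by_region.loc["4002", "rate_per_1000"] == 0.0
    assert np.isnan(voiv.loc[0, "rate_per_100000"])  # count kept, rate omitted


def test_regional_rates_match_groupby_oracle():
    rng = np.random.default_rng(9)
    regions = ["A", "B", "C"]
    labels, patients = [], {}
    for i in range(60):
        pid = f"P{i}"
        labels.append(_label(pid, chronic=bool(rng.random() < 0.5)))
        patients[pid] = _patient(pid, county=str(rng.choice(regions)), voiv="X")
    den = ExternalDenominators(county_populations={r: 1000 for r in regions})
    county, _ = regional_rates(labels, patients, den)
    chronic = {l.patient_id for l in labels if l.chronic_polypharmacy}
    for r in regions:
        brute = sum(1 for p in chronic if patients[p].county_code == r)
        row = county[county.region == r].iloc[0]
        assert row.n_chronic == brute
        assert row.rate_per_1000 == round_half_up(1000 * brute / 1000, 1)


# ------------------------------------------------------------- top drugs ---

def _claim(pid, day, atc):
    return DispensationRecord(pid, day, atc, 1, 30.0)


def test_top_drugs_patient_and_prescription_shares():
    labels = [_label("P1"), _label("P2")]
    claims = [
        _claim("P1", date(2018, 1, 1), "A10BA02"),
        _claim("P1", date(2018, 2, 1), "A10BA02"),
        _claim("P1", date(2018, 3, 1), "A10BA02"),
        _claim("P2", date(2018, 1, 1), "A10BA02"),
        _claim("P2", date(2018, 1, 1), "C10AA05"),
        _claim("P2", date(2018, 2, 1), "C10AA05"),
    ]
    table = top_drugs(claims, labels)
    row_x = table[table.drug_key == "A10BA02"].iloc[0]
    row_y = table[table.drug_key == "C10AA05"].iloc[0]
    assert row_x.pct_patients == 100.0 and row_y.pct_patients == 50.0
    # X holds 4 of 6 prescriptions; a drug on 3 of 6 would print 50.0
    assert row_x.pct_prescriptions == pct(4, 6)
    assert row_y.pct_prescriptions == pct(2, 6)
    assert table.drug_key.tolist() == ["A10BA02", "C10AA05"]  # sorted by patient share


def test_top_drugs_excludes_short_term_groups_and_empty_cohort():
    labels = [_label("P1", chronic=False)]
    assert top_drugs([_claim("P1", date(2018, 1, 1), "A10BA02")], labels).empty
    labels = [_label("P1")]
    table = top_drugs([_claim("P1", date(2018, 1, 1), "J01CA04")], labels)
    assert table.empty


# ------------------------------------------------------------- DDD stats ---

def test_ddd_annual_total_single_patient():
    labels = [_label("P1")]
    patients = {"P1": _patient("P1")}
    claims = [_claim("P1", date(2018, m, 1), "A10BA02") for m in range(1, 13)]  # 12 x 30
    s = ddd_stats(claims, labels, patients)
    assert s.mean_annual == 360.0
    assert s.mean_daily == pytest.approx(360 / 365)


def test_ddd_daily_tail_shares():
    labels = [_label("P1"), _label("P2")]
    patients = {p: _patient(p) for p in ("P1", "P2")}
    claims = [
        DispensationRecord("P1", date(2018, 1, 1), "A10BA02", 1, 3650.0),  # 10.0/day
        DispensationRecord("P2", date(2018, 1, 1), "A10BA02", 1, 365.0),   # 1.0/day
    ]
    s = ddd_stats(claims, labels, patients)
    assert s.n_ge_10_per_day == 1 and s.share_ge_10_per_day == 50.0
    assert s.n_ge_24_per_day == 0


def test_ddd_denominator_days_alive_for_deceased():
    labels = [_label("P1")]
    patients = {"P1": _patient("P1", death=date(2018, 1, 10))}  # 10 days observed
    claims = [DispensationRecord("P1", date(2018, 1, 1), "A10BA02", 1, 100.0)]
    s = ddd_stats(claims, labels, patients)
    assert s.mean_daily == pytest.approx(10.0)
    s2 = ddd_stats(claims, labels, patients, AnalysisConfig(ddd_daily_denominator="full_year"))
    assert s2.mean_daily == pytest.approx(100 / 365)


# ----------------------------------------------------------- utilization ---

def test_utilization_service_shares_and_hospitalisation_rate():
    labels = [_label(f"P{i}") for i in range(10)]
    util = [
        UtilizationRecord("P0", "Psychiatric care and addiction treatment", date(2018, 2, 2), "F32", False),
        UtilizationRecord("P1", "Psychiatric care and addiction treatment", date(2018, 3, 3), "F32", False),
        UtilizationRecord("P2", "Primary healthcare", date(2018, 1, 1), "I10", False),
    ] + [
        UtilizationRecord("P3", "Hospital treatment", date(2018, 4, d), "I50.9", True)
        for d in (1, 2, 3)
    ]
    s = utilization_summary(util, labels)
    svc = s.service_table.set_index("service_type")
    assert svc.loc["Psychiatric care and addiction treatment", "pct_of_cohort"] == 20.0
    # one patient with 3 hospitalisations in a cohort of 10
    assert s.n_hospitalisations == 3
    assert s.hospitalisation_rate_mean == pytest.approx(0.3)
    hosp = s.hospital_diagnoses.iloc[0]
    assert hosp.n_hospitalisations == 3
    assert hosp.pct_of_hospitalisations == 100.0 and hosp.pct_of_cohort == 30.0


def test_utilization_rate_mean_example():
    labels = [_label(p) for p in ("P1", "P2", "P3")]
    util = [
        UtilizationRecord("P3", "Hospital treatment", date(2018, 1, d), "I10", True)
        for d in (1, 2, 3)
    ]
    s = utilization_summary(util, labels)
    assert s.hospitalisation_rate_mean == pytest.approx(1.0)


# ------------------------------------------------------- whole summaries ---

def _pipeline(seed=17, n=150):
    from polyrx.synthetic import GeneratorConfig, generate_cohort

    cohort = generate_cohort(GeneratorConfig(n_patients=n, seed=seed))
    config = AnalysisConfig()
    res = classify_cohort(cohort.claims, cohort.registry(), config)
    return cohort, config, res


def test_summary_self_consistency_and_invariants():
    cohort, config, res = _pipeline()
    summary = build_summary(
        res.labels, res.statuses, cohort.claims, cohort.registry(), config,
        utilization=cohort.utilization,
    )
    # every stored percentage re-derivable from its numerator and denominator
    assert summary.pct_whole_year_of_chronic == pct(
        summary.n_whole_year_elderly, summary.n_chronic_elderly
    )
    assert summary.pct_elderly_of_polypharmacy == pct(
        summary.n_basic_elderly, summary.n_basic_all_ages
    )
    # age-band counts sum to the chronic cohort
    assert summary.age_bands.n.sum() == summary.n_chronic_elderly
    # monthly series bounded by cohort size
    assert all(0 <= c <= summary.n_registry for c in summary.monthly)
    for _, row in summary.drugs.iterrows():
        assert row.pct_patients == pct(row.n_patients, summary.n_chronic_elderly)
    svc = summary.utilization.service_table
    for _, row in svc.iterrows():
        assert row.pct_of_cohort == pct(row.n_patients, summary.n_chronic_elderly)


def test_summaries_permutation_invariant():
    cohort, config, res = _pipeline(seed=23, n=80)
    rng = np.random.default_rng(0)
    shuffled = [cohort.claims[i] for i in rng.permutation(len(cohort.claims))]
    res2 = classify_cohort(shuffled, cohort.registry(), config)
    s1 = build_summary(res.labels, res.statuses, cohort.claims, cohort.registry(), config)
    s2 = build_summary(res2.labels, res2.statuses, shuffled, cohort.registry(), config)
    assert s1.monthly == s2.monthly
    assert s1.n_chronic_elderly == s2.n_chronic_elderly
    assert s1.drugs.equals(s2.drugs)
    assert s1.age_bands.equals(s2.age_bands)


def test_contact_stats_counts_distinct_identifiers():
    labels = [_label("P1")]
    claims = [
        DispensationRecord("P1", date(2018, 1, 1), "A10BA02", 1, 30.0, "DR1", "HC1", "E1"),
        DispensationRecord("P1", date(2018, 2, 1), "A10BA02", 1, 30.0, "DR1", "HC1", "E2"),
        DispensationRecord("P1", date(2018, 3, 1), "C10AA05", 1, 30.0, "DR2", "HC2", "E3"),
    ]
    stats = contact_stats(claims, labels)
    assert stats["prescribers"].mean == 2.0
    assert stats["encounters"].mean == 3.0
    assert stats["providers"].mean == 2.0
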