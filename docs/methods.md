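# Methods

## The operational definitions

`polyrx` classifies patients from reimbursed-drug dispensation claims,
one row per pharmacy dispensation. Three nested labels are produced per
patient and calendar year:

* **Basic polypharmacy.** At least five distinct drugs dispensed within
  six months of the patient's first dispensation of the calendar year.
  "Six months" is implemented as a half-open 183-day window starting at
  the first dispensation; "distinct drug" means a distinct ATC level-5
  substance code, so a fixed-dose combination counts as one drug.
* **Chronic polypharmacy.** A run of at least six consecutive calendar
  months in each of which the patient *possessed* five or more drugs on
  at least 80% of days. Possession on a day means holding dispensed
  supply of the drug on that day.
* **Whole-year persistence.** All twelve months qualify.

Short-term therapy groups are removed before any counting: ATC prefixes
A01, A06, D, J01, J02, J05, J06, J07, P03 and V. The list ships as
configuration data and every threshold (5 drugs, 80%, 6 months, the
elderly cut-off of 65 years) is a config field.

## From dispensations to possession

Days of supply per dispensation = floor(packs × DDD-per-pack /
assumed daily consumption), minimum one day. The assumed consumption is
1 DDD/day per drug — the WHO drug-utilization convention — and is
configurable per analysis, not per drug (prescribed daily doses are not
in claims data).

Per patient-drug pair, supply events are stitched into covered-day
intervals under one of two carryover policies:

* `shift_forward` (default): an early refill is stockpiled — its supply
  starts the day after the prior supply ends. Total covered days then
  always equal total dispensed supply days, which is the standard
  proportion-of-days-covered (PDC) convention and the only reading under
  which "period covered by dispensed drug supply" is conserved.
* `truncate`: each dispensation covers its own `[start, start+days-1]`
  range and overlaps are unioned; provided for sensitivity analysis.

Daily concurrency is the number of distinct drug keys covering each day.
A month qualifies when the count of days with concurrency ≥ 5 reaches
80% of the month's civil-calendar days. The ≥ test is integer
cross-multiplication on the exact rational threshold (`days×5 ≥
4×days_in_month` for 0.8), so there is no floating-point boundary
ambiguity: 24/30 qualifies, 24/31 does not, 25/31 does.

Two readings of the monthly criterion exist and both are implemented.
The default `day_concurrency` mode requires five drugs *simultaneously*
possessed on 80% of days (this is what a monthly qualifying-patient
series counts). The alternative `per_drug` mode requires at least five
drugs to *each* be possessed on 80% of the month's days. The day-level
reading is the stricter and is the default; the choice is a config
switch because claims-based prevalence studies are not consistent on
this point.

Deaths censor possession: coverage is clipped at the death date, so
months after death cannot qualify, while the patient stays in the cohort
and is classified on the observed months.

A lookback window (default 0 days) can admit late-prior-year
dispensations so that coverage at the year start is not artificially
censored. The default is no lookback — the basic-polypharmacy anchor is
always the first dispensation *within* the year — and with no lookback
January is structurally the month with the least accumulated coverage.

### A boundary subtlety

Chronic does not *strictly* imply basic: a fifth drug first dispensed
on day 184–188 after the patient's first dispensation falls outside the
183-day basic window yet can still (just) support six qualifying months
July–December. The implication holds for any cohort whose chronic
regimens are dispensed from the start of their qualifying window — as in
the synthetic cohorts — and is asserted there, not universally.

## Descriptive layer

All summaries are count arithmetic with explicit denominators stored
next to every percentage; `verify_ratio` re-derives any percentage from
its numerator and denominator, which is how internally inconsistent
published cells are detected and flagged rather than matched. Rounding
is decimal half-up, one decimal for percentages. Standard deviations are
sample (n−1) by default — a config switch, since descriptive reports
rarely state which was used.

Per-patient daily DDD consumption divides the annual dispensed DDD total
by the days the patient was alive in the study year (365 for survivors);
an always-365 divisor is available. Published annual/daily DDD pairs are
not always mutually consistent under any single divisor, which is
precisely why the divisor is exposed rather than silently reconciled.

## The synthetic cohort generator

There is no public claims dataset of this kind — national payer data are
confidential — so the generator emulates the three input tables with
*designed* ground truth:

* **Strata.** Each patient is designed `chronic` (default 19% of the
  cohort), `basic_only` (24%), or `neither`, so that basic prevalence
  lands near 43% of the elderly and chronic near one fifth. 68.6% of
  chronic designs persist the whole year.
* **Chronic refills.** One 30-day supply per regimen drug at the start
  of every month of the designed qualifying window, start day jittered
  by ≤ `refill_jitter_days` (default 2; 0 gives mathematically
  guaranteed recovery). Windows shorter than twelve months start later
  in the year with probability proportional to the start month, loosely
  emulating the seasonal accumulation of qualifying patients (January
  lowest, December high) seen when no supply carries into the year.
* **Regimens.** Drawn by independent Bernoulli inclusion at the seeded
  per-drug patient shares (20 common chronic-therapy substances), topped
  up from a disjoint filler pool to the size target drawn from the
  regimen-size distribution (mean ≈ 8 drugs). Bernoulli inclusion keeps
  the seeded shares recoverable without bias by the top-drug summary —
  weighted sampling of a fixed-size regimen would distort them.
* **Basic-only patients** receive 5–7 distinct drugs staggered 33 days
  apart inside a 183-day window: enough distinct drugs for the basic
  label, never five concurrent. **Neither** patients get at most four
  distinct drugs. Refill gaps (`gap_probability`) apply to non-chronic
  designs only, so designed chronic labels stay exact.
* **Noise.** Every stratum receives excluded-ATC rows (antibiotics,
  laxatives, dermatologicals, …) which must never change any label.
* **Deaths.** ≈ 3.9% of the cohort dies in October–December (never the
  whole-year stratum; all dispensations precede death), exercising the
  censoring path without breaking designed labels.
* **Utilization.** Service contacts are Bernoulli-present per service
  type at chronic-cohort shares, with ICD-10 principal diagnoses drawn
  from seeded outpatient and hospitalisation weight tables, and
  hospitalisation counts tuned to a mean near 1 per chronic patient.

What the generator does **not** emulate: dose titration and per-drug
daily doses other than 1 DDD/day, therapy switching within a class,
seasonal prescribing beyond the window-start bias, regional prevalence
differences (regions are assigned independently of stratum), and any
correlation between regimen content and diagnoses. Passing recovery
tests therefore validates the *pipeline mechanics* — interval stitching,
thresholding, run detection, censoring, summary arithmetic — not the
epidemiology of any real population.

## Validation strategy

* **Oracle equivalence.** Interval-based covered days, daily concurrency
  and monthly qualification are checked against a day-by-day stock
  simulation (supply added on dispensing days, one unit consumed per
  day) on a thousand random patients, under both carryover policies, and
  property-tested with hypothesis at small sizes.
* **Ground-truth recovery.** With perfect monthly refills (jitter 0, no
  gaps) the classifier recovers designed chronic labels with sensitivity
  and specificity exactly 1.0 on a 2,000-patient cohort; deleting half
  of all chronic refills collapses the recovered count, tracing the
  sensitivity of an 80%-possession rule to adherence.
* **Properties.** Supply conservation under `shift_forward`;
  monotonicity (an added dispensation never lowers any day's concurrency
  or any month's qualifying-day count); permutation invariance of
  classification and summaries; excluded-ATC no-op end to end;
  write-then-read identity for every table.

Problem sizes in the test suite (500–2,000 synthetic patients, 1,000
random oracle patients) were chosen as the smallest cohorts at which
binomial noise on recovered shares is clearly below the assertion
margins; the pipeline itself is linear in claims and runs national-scale
inputs out of the box.

## Known limitations

* Only reimbursed, dispensed drugs are visible — the same conservative
  bias as the payer data the package targets (no OTC, no non-reimbursed
  prescriptions, no unfilled prescriptions).
* The 1 DDD/day assumption misstates supply duration for drugs dosed far
  from their DDD; it is uniform by design, not per-drug.
* Ages are computed from birth year only (registry granularity), so the
  elderly cut-off is a year-of-birth rule.
* Chronic runs are searched within a single calendar year; a run
  spanning December–May across two years is out of scope of the one-year
  data frame.
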