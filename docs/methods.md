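# Methods

## Data model

Claims are held as six typed tables (`sdre.claims_model.ClaimsDatabase`)
mirroring a German statutory-insurance research extract: insurants (birth
year, sex, enrollment interval, death date), outpatient diagnoses billed per
calendar quarter (`YYYYQn`), day-dated dispensations (7-character ATC code),
inpatient admissions (day-dated, ICD-10-GM primary/secondary codes, OPS
procedure codes, DRG case cost), quarterly physician contacts by specialty,
and ancillary cost items. The sixth table (ancillary/equipment/dialysis
items, plus a `cost` column on dispensations) exists because the direct-cost
report is broken down into inpatient, medication, outpatient, ancillary,
equipment and dialysis components, and the first five tables carry no money
for the last four; it is optional on disk, so five-table extracts still load.

Conventions fixed once and used everywhere:

* Length of stay counts both admission and discharge day
  (`discharge − admit + 1`); a same-day admission is 1 day. This matches
  German per-case billing and keeps day totals integral.
* Dates are ISO-8601; quarterly records are assigned to intervals by the
  quarter midpoint (day 45). ICD/ATC/OPS matching is case-insensitive prefix
  matching on uppercased strings; ICD ranges like `S00–S09` match on the
  three-character category.
* Dispensations carry day-level dates (the index date is a prescription
  date, so day precision is required even though outpatient diagnoses are
  quarterly).

## Phenotype

An SDRE case needs (a) ≥1 diagnosis with prefix `G40` in any setting, any
position, at any time in the observation window, and (b) an index date: the
earliest dispense date *d* in the identification interval
(2009-01-01..2010-12-31) such that ≥4 distinct N03A substances have at least
one dispensation inside the half-open window `(d − 548 d, d]`. Points that
were genuinely open and were decided here:

* "Different" drugs are counted at the ATC substance level (7 characters);
  benzodiazepines count only when N03A-coded (clonazepam N03AE01 yes,
  lorazepam N05BA06 never).
* Window membership requires a dispensation *inside* the window, not a
  first-ever dispensation inside it — the literal reading of "four
  different drugs in an 18-month period". A substance started long before
  the window still counts if it was re-dispensed inside.
* Substances dispensed before 2009 may contribute; only the index (the
  window end) must fall in 2009–2010, because the index is what anchors
  follow-up.
* No temporal link between the epilepsy diagnosis and the drug window is
  required, and no continuous-enrollment filter is applied; instead every
  proportion is reported with its at-risk denominator.
* 18 months is implemented as 548 days; follow-up years are 365-day blocks
  from index, not calendar years (a calendar mode exists for the cost
  report, whose reference figures were billed per calendar year 2011–2013).

The scan is verified against a brute-force window enumeration on fuzzed
prescription histories, and satisfies two structural properties: adding a
dispensation can only move the index earlier, and shifting all dates shifts
the index equally.

## Matching

Exact matching on (birth year, sex) at ratio 20:1, sampling uniformly
without replacement among insurants with no `G40` diagnosis ever, who are
not cases and are enrolled on the case's index date. Whether the reference
design matched with or without replacement is not stated; without
replacement is implemented, and exhausted pools are recorded as shortfalls
rather than padded. Each case owns an RNG sub-stream derived from the global
seed and its insurant id: the candidate ordering of a case does not depend
on which other cases exist, so removing a case leaves other cases' control
sets unchanged whenever strata do not compete (exactly guaranteed for
disjoint strata; approximately under ample pools). Cases compete for scarce
controls in ascending insurant-id order. A `age_tolerance_years` option
widens the birth-year stratum for small pools; the default is exact year.

Controls inherit the case's index date as pseudo-index. Control follow-up
and survival are measured from that pseudo-index.

## Burden metrics

A person is **at risk** in a period iff alive and enrolled at the period
start; exposure days are truncated at death/disenrollment. Denominators are
the at-risk counts and are reported next to every numerator so alternative
conventions can be recomputed. Day-dated events belong to the period
containing their date; admissions are assigned by admit date and never split
across boundaries (whole-case accounting, as in DRG billing). Prescription
"shares" count a patient once per period per substance. Cost components are
rounded to the cent per component and the total is defined as the component
sum, so conservation holds exactly. Every summary is checked against a naive
per-patient loop on small databases.

Code sets for comorbidity labels without a canonical ICD block are explicit
assumptions, editable via a config file (`name = CODE; CODE–CODE; ...`):
depression F32–F33, vascular disorders I60–I79 + G45, gastrointestinal
K20–K93, hypertension I10–I15. Injury blocks follow the standard chapters
(head S00–S09, trunk/limb T08–T14, knee/lower leg S80–S89, ankle/foot
S90–S99).

## Statistics

The Pearson chi-square for 2×2 tables (Σ(O−E)²/E, df = 1, two-sided p from
the χ² survival function; Yates correction off by default since the
reference analysis does not mention one) and the Kaplan–Meier product-limit
estimator (censored-at-t subjects remain at risk for events at t; Greenwood
variance) are implemented directly and cross-checked in the tests against
scipy and lifelines. Cumulative mortality at a horizon is 1 − S(h) using the
step value at the largest event time ≤ h. No multiple-testing adjustment is
applied (explorative analyses). A log-rank test is provided as an extra for
curve comparisons; it is not part of the core report. Deaths on the index
day get duration 1 (positive durations are required).

## Synthetic cohort generator

The generator (`sdre.synthetic_claims`) emulates the structure of a 5%
statutory-insurance sample over 2008–2013 and encodes the study conditions
as defaults. Its purpose is recoverability — every downstream estimate can
be compared with a configured truth — not demographic realism.

* **Population**: a coarse age/sex pyramid; enrollment covers the whole
  window except a 2% fraction with a late start or early end (real
  insurance churn rules are unknowable; this is a knob, not a claim).
* **Drug histories** are a per-patient process over substances: scheduled
  accrual of the first four substances with a first-to-fourth latency drawn
  from a truncated normal (212 ± 136.2 days) and the fourth landing in the
  identification interval; quarterly refills (90 ± 10 days) while a
  substance stays active (geometric lifetime, mean 7 quarters); further
  additions at a per-quarter switch probability of 0.20 for refractory vs
  0.04 for non-refractory patients. By default non-refractory patients are
  capped at 3 lifetime substances, making the phenotype exactly learnable;
  removing the cap creates an overlapping regime in which identification is
  only ~95%+ sensitive/specific relative to the assigned labels.
* **Admissions**: annual counts are gamma-Poisson (per-patient frailty
  shared across years), so the implied annual probability of ≥1 admission
  is 1 − (k/(k+μ))^k: μ = 1.04, k = 0.8 for cases (≈49%/year, ≈4.3
  admissions per 3-year-hospitalized patient) and μ = 0.183, k = 0.19 for
  the background (≈12%/year). 41.7% of case admissions carry an epilepsy
  primary code (10% of those status epilepticus G41); lengths of stay are
  lognormal with mean 9.7 days (cases) / 7.5 (background).
* **Mortality**: piecewise-constant from the scheduled index for refractory
  patients — 7.8% cumulative in follow-up year 1, 14% by year 3 — and
  exponential background at 0.00707/year (≈2.1% over three years)
  otherwise. Deaths falling outside a patient's enrollment are unobserved,
  as in real claims.
* **Comorbidity** is sprinkled as independent annual Bernoulli draws per
  ICD block with case/control probabilities (depression 0.28/0.10, head
  injury 0.16/0.03, hypertension 0.30/0.30, …). There is no within-patient
  correlation, and because draws are per calendar year while cohort years
  straddle two calendar years, index-anchored annual prevalence runs
  slightly below the configured rate — a known, documented dilution.
* **Costs** are lognormal per event (DRG mean €5,300 for cases, AED pack
  mean €410, contact €75, plus ancillary/equipment/dialysis items), chosen
  so that a case-year totals roughly €12–14k with ≈40% inpatient and ≈35%
  medication share.

One `SeedSequence` per run spawns fixed-order sub-streams per table, so
identical parameters and seed give byte-identical CSVs. `default_params`
offers `small` (n = 20,000, refractory fraction 0.10 of epileptics) and
`reference` (n = 200,000, refractory fraction 0.024, i.e. the expected
case yield of ≈1.9 per 10,000 insured implied by 769 cases in 4 million).

**What passing tests do and do not show.** The generator produces exactly
the kind of signal the pipeline looks for; recovery of its labels and rates
demonstrates the pipeline's correctness, not the clinical validity of the
phenotype on real data (claims cannot distinguish refractoriness from, say,
switching due to adverse events — no sensitivity/specificity for the case
definition itself is obtainable).

## Problem sizes

Tests run the generator at 300–20,000 insurants; the analysis scripts and
the acceptance script use 20,000 insurants (≈200 cases, ≈4,000 controls),
which gives stable rates while keeping a full run under a minute. Fuzzed
oracle checks use 500–1,000 random instances each.

## Known limitations

* Control direct costs are computed with the same machinery as case costs
  but the reference cost figures are case-only, so no cost comparison is
  asserted anywhere.
* The generator models no billing artifacts (co-payments, risk-pool
  adjustments), no realistic DRG catalog, and no seasonal or age structure
  in event rates.
* Epilepsy syndrome classification from ICD-10 codes is deliberately out of
  scope, as is propensity-score matching and any indirect/intangible cost
  estimation.
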