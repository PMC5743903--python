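#!/usr/bin/env python
"""Resource use, comorbidity and cost burden of SDRE vs matched controls.

Computes per-period hospitalization, procedure uptake, prescription shares,
outpatient contacts, comorbidity prevalence (with chi-square tests) and
direct-cost components for both cohorts. Writes results/04_burden.csv,
results/04_comorbidity.csv and results/04_costs.csv.
"""

from datetime import date
from pathlib import Path

import pandas as pd

from sdre.burden import (
    contact_summary,
    cost_summary,
    costs_to_frame,
    default_code_sets,
    hospitalization_summary,
    prescription_pattern,
    prevalence_compare,
    procedure_uptake,
    status_epilepticus_hospitalized,
)
from sdre.claims_model import load_claims
from sdre.stats import format_p

ROOT = Path(__file__).resolve().parent.parent

db = load_claims(ROOT / "scratch" / "claims")
cases = pd.read_csv(ROOT / "results" / "02_cases.csv", dtype={"insurant_id": str})
matched = pd.read_csv(ROOT / "results" / "03_matched.csv", dtype={"case_id": str, "control_id": str})
case_anchors = {r.insurant_id: date.fromisoformat(r.index_date) for r in cases.itertuples()}
control_anchors = {r.control_id: date.fromisoformat(r.pseudo_index) for r in matched.itertuples()}

frames = []
for label, anchors in (("sdre", case_anchors), ("control", control_anchors)):
    frames.append(hospitalization_summary(db, anchors, cohort=label))
    frames.append(hospitalization_summary(db, anchors, epilepsy_specific=True, cohort=label))
    frames.append(contact_summary(db, anchors, cohort=label))
frames.append(procedure_uptake(db, case_anchors, ["8-972", "1-210", "1-211", "5-010"]))
burden = pd.concat(frames, ignore_index=True)
burden.to_csv(ROOT / "results" / "04_burden.csv", index=False)

shares, rx_stats = prescription_pattern(db, case_anchors)
shares.to_csv(ROOT / "results" / "04_prescriptions.csv", index=False)

com_rows = [
    prevalence_compare(db, case_anchors, control_anchors, cs, "fu1")
    for cs in default_code_sets().values()
]
com = pd.DataFrame(com_rows)
com.to_csv(ROOT / "results" / "04_comorbidity.csv", index=False)

costs = pd.concat(
    [
        costs_to_frame(cost_summary(db, anchors, cohort=label), cohort=label)
        for label, anchors in (("sdre", case_anchors), ("control", control_anchors))
    ],
    ignore_index=True,
)
costs.to_csv(ROOT / "results" / "04_costs.csv", index=False)


def pick(cohort, period, metric):
    m = burden[(burden.cohort == cohort) & (burden.period == period) & (burden.metric == metric)]
    return float(m["value"].iloc[0]) if len(m) else float("nan")


print(f"cohorts: {len(case_anchors)} cases, {len(control_anchors)} controls")
for y in ("fu1", "fu2", "fu3"):
    print(f"  hospitalization {y}: sdre {pick('sdre', y, 'hospitalized_share'):.1%}"
          f" vs control {pick('control', y, 'hospitalized_share'):.1%}")
k, n, prop = status_epilepticus_hospitalized(db, case_anchors)
print(f"  status epilepticus admissions: {k}/{n} = {prop:.1%} of cases over follow-up")
print(f"  distinct AEDs over follow-up: mean {rx_stats['distinct_aeds_fu_mean']:.1f}"
      f" (SD {rx_stats['distinct_aeds_fu_sd']:.1f})")
for r in com.itertuples():
    print(f"  {r.code_set}: {r.p_case:.1%} vs {r.p_control:.1%} (p {format_p(r.p_value)})")
sdre_fu1 = costs[(costs.cohort == "sdre") & (costs.period == "fu1")].iloc[0]
print(f"  direct costs per case, follow-up year 1: EUR {sdre_fu1.mean_total_per_person:,.0f}"
      f" (inpatient share {sdre_fu1.inpatient / sdre_fu1.total:.0%})")
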