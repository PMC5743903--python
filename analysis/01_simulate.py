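#!/usr/bin/env python
"""Generate the synthetic claims cohort the downstream analyses run on.

Simulates 20,000 insurants (2008-2013, quarterly billing structure) with an
epileptic subgroup of which half are severely drug-refractory, writes the
claims tables to scratch/claims/ and a small population summary to
results/01_population.csv.
"""

from pathlib import Path

import pandas as pd

from sdre.claims_model import validate, write_claims
from sdre.synthetic_claims import SimulationParams, simulate_claims

ROOT = Path(__file__).resolve().parent.parent
SEED = 7

params = SimulationParams(
    n_insurants=20_000, epilepsy_prevalence=0.02, refractory_fraction=0.5, seed=SEED
)
db, truth = simulate_claims(params)
violations = validate(db)
assert not violations, violations[:3]

out = ROOT / "scratch" / "claims"
write_claims(db, out)
truth.frame.to_csv(out / "ground_truth.csv", index=False)

f = truth.frame
summary = pd.DataFrame(
    [
        ("insurants", len(f)),
        ("epileptic", int(f.has_epilepsy.sum())),
        ("refractory_ground_truth", int(f.is_refractory.sum())),
        ("deaths_observed", int((f.death_date != "").sum())),
        ("dispensations", len(db.dispensations)),
        ("admissions", len(db.admissions)),
    ],
    columns=["quantity", "count"],
)
(ROOT / "results").mkdir(exist_ok=True)
summary.to_csv(ROOT / "results" / "01_population.csv", index=False)
print(f"wrote claims for {len(f)} insurants to {out}")
print(summary.to_string(index=False))
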