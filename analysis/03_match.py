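#!/usr/bin/env python
"""Draw the 20:1 age/sex exact-matched epilepsy-free comparison cohort.

Controls inherit the case's index date as pseudo-index. Writes
results/03_matched.csv (pairs) and prints the match balance.
"""

from datetime import date
from pathlib import Path

import pandas as pd

from sdre.claims_model import load_claims
from sdre.matching import match_controls, matched_to_frame
from sdre.phenotyping import SdreCase

ROOT = Path(__file__).resolve().parent.parent

db = load_claims(ROOT / "scratch" / "claims")
cases_df = pd.read_csv(ROOT / "results" / "02_cases.csv", dtype={"insurant_id": str})
cases = [
    SdreCase(r.insurant_id, date.fromisoformat(r.index_date), frozenset(r.substances.split(";")))
    for r in cases_df.itertuples()
]

cohort = match_controls(db, cases, ratio=20, seed=11)
matched_to_frame(cohort).to_csv(ROOT / "results" / "03_matched.csv", index=False)

achieved = len(cohort.pairs) / len(cases) if cases else 0
print(f"matched {len(cohort.pairs)} controls to {len(cases)} cases "
      f"(achieved ratio {achieved:.2f}:1, {len(cohort.shortfalls)} strata with shortfall)")
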