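"""Age/sex exact-matched comparison cohort for SDRE cases.

Controls are drawn without replacement from insurants with the same birth
year and sex as the case, no epilepsy-prefix diagnosis in any setting at any
time, who are not cases themselves and are enrolled on the case's index date.
Each matched control inherits the case's index date as its pseudo-index so
that follow-up years are defined for both cohorts.

Sampling uses one RNG sub-stream per case (derived from the global seed and
the case id), so a case's candidate ordering does not depend on which other
cases exist; when strata are not exhausted this makes per-case control sets
stable under removal of other cases.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .claims_model import ClaimsDatabase
from .phenotyping import SdreCase

__all__ = ["MatchedCohort", "match_controls", "matched_to_frame"]


@dataclass
class MatchedCohort:
    pairs: list[tuple[str, str]]  # (case_id, control_id)
    ratio: int
    pseudo_index: dict[str, date]  # control_id -> case's index date
    shortfalls: dict[str, int] = field(default_factory=dict)  # case_id -> achieved

    @property
    def control_ids(self) -> list[str]:
        return [c for _, c in self.pairs]

    def controls_of(self, case_id: str) -> list[str]:
        return [c for k, c in self.pairs if k == case_id]


def _case_stream(seed: int, case_id: str) -> np.random.Generator:
    digest = hashlib.sha256(case_id.encode()).digest()[:4]
    sub = int.from_bytes(digest, "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, sub]))


def match_controls(
    db: ClaimsDatabase,
    cases: list[SdreCase],
    ratio: int = 20,
    seed: int = 0,
    epilepsy_icd_prefix: str = "G40",
    age_tolerance_years: int = 0,
) -> MatchedCohort:
    """Draw up to ``ratio`` controls per case, exactly matched on birth year
    (widened to +/- ``age_tolerance_years`` if requested) and sex.

    Cases compete for scarce controls in ascending insurant-id order; a pool
    exhausted before ``ratio`` is reached is recorded in ``shortfalls`` and
    never padded.
    """
    ins = db.insurants
    dx = db.diagnoses
    epileptic = set(
        dx.loc[
            dx["icd_code"].astype(str).str.upper().str.startswith(epilepsy_icd_prefix.upper()),
            "insurant_id",
        ]
    )
    case_ids = {c.insurant_id for c in cases}

    eligible = ins[~ins["insurant_id"].isin(epileptic | case_ids)].copy()
    eligible["enroll_start"] = pd.to_datetime(eligible["enroll_start"])
    eligible["enroll_end"] = pd.to_datetime(eligible["enroll_end"])
    by_stratum = {
        key: grp.sort_values("insurant_id")
        for key, grp in eligible.groupby(["birth_year", "sex"], sort=False)
    }

    case_attrs = ins.set_index("insurant_id")[["birth_year", "sex"]]
    pairs: list[tuple[str, str]] = []
    pseudo_index: dict[str, date] = {}
    shortfalls: dict[str, int] = {}
    used: set[str] = set()

    for case in sorted(cases, key=lambda c: c.insurant_id):
        birth_year = int(case_attrs.loc[case.insurant_id, "birth_year"])
        sex = case_attrs.loc[case.insurant_id, "sex"]
        idx_ts = pd.Timestamp(case.index_date)
        frames = [
            by_stratum[(y, sex)]
            for y in range(birth_year - age_tolerance_years, birth_year + age_tolerance_years + 1)
            if (y, sex) in by_stratum
        ]
        if frames:
            pool = pd.concat(frames) if len(frames) > 1 else frames[0]
            pool = pool[(pool["enroll_start"] <= idx_ts) & (pool["enroll_end"] >= idx_ts)]
            candidates = pool["insurant_id"].to_numpy()
        else:
            candidates = np.array([], dtype=object)

        rng = _case_stream(seed, case.insurant_id)
        order = rng.permutation(len(candidates))
        taken: list[str] = []
        for j in order:
            cid = str(candidates[j])
            if cid in used:
                continue
            taken.append(cid)
            if len(taken) == ratio:
                break
        for cid in taken:
            used.add(cid)
            pairs.append((case.insurant_id, cid))
            pseudo_index[cid] = case.index_date
        if len(taken) < ratio:
            shortfalls[case.insurant_id] = len(taken)

    return MatchedCohort(pairs=pairs, ratio=ratio, pseudo_index=pseudo_index, shortfalls=shortfalls)


def matched_to_frame(cohort: MatchedCohort) -> pd.DataFrame:
    """Tabular form written to matched.csv."""
    return pd.DataFrame(
        {
            "case_id": [k for k, _ in cohort.pairs],
            "control_id": [c for _, c in cohort.pairs],
            "pseudo_index": [cohort.pseudo_index[c].isoformat() for _, c in cohort.pairs],
        }
    )
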