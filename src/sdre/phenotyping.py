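"""Phenotyping of severely drug-refractory epilepsy (SDRE) from claims.

A case is an insurant with (a) at least one coded epilepsy diagnosis (ICD-10
G40*) anywhere in the observation window and (b) dispensations of at least
``k_distinct`` different anticonvulsant substances (ATC N03A, 7-character
substance level) within a rolling 18-month (548-day) window, the window end
falling in the identification interval. The dispense date on which the k-th
distinct substance is on board — the index date — anchors a 1-year baseline
and three 365-day follow-up years.

"Different" substances are counted at the full 7-character ATC code; a
substance is in a window if it has at least one dispensation inside the
half-open window ``(d - window_days, d]``. Benzodiazepines only count when
they carry an N03A code (e.g. clonazepam N03AE01); N05-coded ones never do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

from .claims_model import ClaimsDatabase

__all__ = [
    "PhenotypeConfig",
    "SdreCase",
    "distinct_substance_accrual",
    "find_index_date",
    "identify_sdre_cases",
    "cases_to_frame",
]


@dataclass(frozen=True)
class PhenotypeConfig:
    epilepsy_icd_prefix: str = "G40"
    aed_atc_prefix: str = "N03A"
    k_distinct: int = 4
    window_days: int = 548  # 18 months
    identification_start: date = date(2009, 1, 1)
    identification_end: date = date(2010, 12, 31)
    baseline_days: int = 365
    followup_years: int = 3
    year_days: int = 365

    def __post_init__(self) -> None:
        if self.k_distinct < 2:
            raise ValueError("k_distinct must be at least 2")
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if self.identification_start > self.identification_end:
            raise ValueError("identification interval is empty")


@dataclass(frozen=True)
class SdreCase:
    """A phenotyped case with its index-anchored interval layout."""

    insurant_id: str
    index_date: date
    qualifying_substances: frozenset[str]
    baseline: tuple[date, date] = field(init=False)  # [start, end) half-open
    followup: tuple[tuple[date, date], ...] = field(init=False)

    def __post_init__(self) -> None:
        base = (self.index_date - timedelta(days=365), self.index_date)
        fu = tuple(
            (
                self.index_date + timedelta(days=365 * (y - 1)),
                self.index_date + timedelta(days=365 * y),
            )
            for y in (1, 2, 3)
        )
        object.__setattr__(self, "baseline", base)
        object.__setattr__(self, "followup", fu)

    @property
    def followup_span(self) -> tuple[date, date]:
        return self.followup[0][0], self.followup[-1][1]


def _as_date(x) -> date:
    if isinstance(x, pd.Timestamp):
        return x.date()
    return x


def distinct_substance_accrual(
    dispensations: pd.DataFrame, atc_prefix: str = "N03A"
) -> list[tuple[str, date]]:
    """First dispense date of each distinct prefix-matching substance for one
    insurant, sorted by first dispense date (ties by ATC code)."""
    if len(dispensations) == 0:
        return []
    rx = dispensations[
        dispensations["atc_code"].astype(str).str.upper().str.startswith(atc_prefix.upper())
    ]
    if len(rx) == 0:
        return []
    firsts = rx.groupby("atc_code")["dispense_date"].min()
    items = sorted(
        ((code, _as_date(d)) for code, d in firsts.items()), key=lambda t: (t[1], t[0])
    )
    return items


def find_index_date(
    dispensations: pd.DataFrame, config: PhenotypeConfig | None = None
) -> tuple[date, frozenset[str]] | None:
    """Earliest dispense date d in the identification interval such that at
    least ``k_distinct`` different substances have a dispensation inside
    ``(d - window_days, d]``; returns (d, substances in that window) or None.
    """
    config = config or PhenotypeConfig()
    if len(dispensations) == 0:
        return None
    rx = dispensations[
        dispensations["atc_code"].astype(str).str.upper().str.startswith(config.aed_atc_prefix.upper())
    ]
    if len(rx) == 0:
        return None
    pairs = sorted(
        {(_as_date(d), str(c)) for d, c in zip(rx["dispense_date"], rx["atc_code"])}
    )
    dates = [p[0] for p in pairs]
    window = timedelta(days=config.window_days)
    for d in sorted({d for d in dates if config.identification_start <= d <= config.identification_end}):
        lo = d - window
        in_window = {c for (dd, c) in pairs if lo < dd <= d}
        if len(in_window) >= config.k_distinct:
            return d, frozenset(in_window)
    return None


def identify_sdre_cases(
    db: ClaimsDatabase, config: PhenotypeConfig | None = None
) -> list[SdreCase]:
    """Run the case definition over a whole database.

    Requires the epilepsy diagnosis (any setting, any position, any time in
    the observation window), a successful window scan, and enrollment
    covering the index date. Cases are returned sorted by insurant id.
    """
    config = config or PhenotypeConfig()
    prefix = config.epilepsy_icd_prefix.upper()
    dx = db.diagnoses
    epileptic_ids = set(
        dx.loc[dx["icd_code"].astype(str).str.upper().str.startswith(prefix), "insurant_id"]
    )
    if not epileptic_ids:
        return []

    enroll = db.insurants.set_index("insurant_id")[["enroll_start", "enroll_end"]]
    cases: list[SdreCase] = []
    rx_all = db.dispensations
    rx_epi = rx_all[rx_all["insurant_id"].isin(epileptic_ids)]
    for insurant_id, rx in rx_epi.groupby("insurant_id", sort=True):
        hit = find_index_date(rx, config)
        if hit is None:
            continue
        index_date, substances = hit
        if insurant_id not in enroll.index:
            continue
        row = enroll.loc[insurant_id]
        if not (_as_date(row["enroll_start"]) <= index_date <= _as_date(row["enroll_end"])):
            continue
        cases.append(SdreCase(str(insurant_id), index_date, substances))
    return cases


def cases_to_frame(cases: list[SdreCase]) -> pd.DataFrame:
    """Tabular form written to cases.csv."""
    return pd.DataFrame(
        {
            "insurant_id": [c.insurant_id for c in cases],
            "index_date": [c.index_date.isoformat() for c in cases],
            "n_qualifying_substances": [len(c.qualifying_substances) for c in cases],
            "substances": [";".join(sorted(c.qualifying_substances)) for c in cases],
        }
    )
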