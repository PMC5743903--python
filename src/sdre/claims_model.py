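"""Domain model for statutory health-insurance claims tables.

The claims database mirrors the structure of a German sickness-fund research
database: an insurant master table plus longitudinal tables for outpatient
diagnoses (billed by calendar quarter), drug dispensations (day-dated, ATC
coded), inpatient admissions (day-dated, ICD/OPS coded, with a DRG case cost),
outpatient physician contacts (quarterly, by specialty) and ancillary cost
items. All tables are held as pandas DataFrames with typed columns; dates are
ISO-8601, quarters are encoded ``YYYYQn``.

Everything is plain delimited text on disk: one CSV per table plus a small
JSON metadata file carrying the observation window.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClaimsDataError",
    "ClaimsDatabase",
    "Violation",
    "load_claims",
    "write_claims",
    "validate",
    "quarter_of_date",
    "quarter_start",
    "quarter_midpoint",
    "parse_quarter",
]

SEXES = ("female", "male")
SETTINGS = ("inpatient", "outpatient")
POSITIONS = ("primary", "secondary")
SPECIALTIES = (
    "general_practitioner",
    "neurologist",
    "neuropsychiatrist",
    "neuropediatrician",
    "radiologist",
    "other",
)
ANCILLARY_CATEGORIES = ("ancillary", "equipment", "dialysis")

ICD_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")
QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

# column layouts for the on-disk CSV files (order is the write order)
TABLE_COLUMNS = {
    "insurants": ["insurant_id", "birth_year", "sex", "enroll_start", "enroll_end", "death_date"],
    "diagnoses": ["insurant_id", "quarter", "icd_code", "setting", "position"],
    "dispensations": ["insurant_id", "dispense_date", "atc_code", "substance_name", "cost"],
    "admissions": [
        "insurant_id", "admit_date", "discharge_date", "primary_icd",
        "secondary_icds", "ops_codes", "drg_cost",
    ],
    "outpatient_contacts": [
        "insurant_id", "quarter", "specialty", "n_contacts", "prescriber_of_aed", "cost",
    ],
    "ancillary": ["insurant_id", "service_date", "category", "cost"],
}

TABLE_FILES = {
    "insurants": "insurants.csv",
    "diagnoses": "diagnoses.csv",
    "dispensations": "dispensations.csv",
    "admissions": "admissions.csv",
    "outpatient_contacts": "outpatient.csv",
    "ancillary": "ancillary.csv",
}

DATE_COLUMNS = {
    "insurants": ["enroll_start", "enroll_end", "death_date"],
    "dispensations": ["dispense_date"],
    "admissions": ["admit_date", "discharge_date"],
    "ancillary": ["service_date"],
}


class ClaimsDataError(Exception):
    """Fatal structural problem in a claims table (missing file, bad value)."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which table, which row, which rule."""

    table: str
    row: int
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        msg = f"{self.table}[{self.row}]: {self.rule}"
        return f"{msg} ({self.detail})" if self.detail else msg


def quarter_of_date(d: date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def parse_quarter(q: str) -> tuple[int, int]:
    m = QUARTER_RE.match(q)
    if not m:
        raise ClaimsDataError(f"malformed quarter {q!r} (expected YYYYQn)")
    return int(m.group(1)), int(m.group(2))


def quarter_start(q: str) -> date:
    year, n = parse_quarter(q)
    return date(year, 3 * (n - 1) + 1, 1)


def quarter_midpoint(q: str) -> date:
    """Day 45 of the quarter; used to assign quarterly records to intervals."""
    return quarter_start(q) + timedelta(days=45)


def _empty(table: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[table]})


@dataclass
class ClaimsDatabase:
    """Container of the six claims tables plus the observation window.

    ``ancillary`` is optional on disk; a missing file is read as an empty
    table so older five-table extracts still load.
    """

    insurants: pd.DataFrame
    diagnoses: pd.DataFrame
    dispensations: pd.DataFrame
    admissions: pd.DataFrame
    outpatient_contacts: pd.DataFrame
    observation_start: date
    observation_end: date
    ancillary: pd.DataFrame = field(default_factory=lambda: _empty("ancillary"))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_FILES}

    def row_counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables().items()}

    def subset(self, insurant_ids) -> "ClaimsDatabase":
        """Restrict every table to the given insurants (copy)."""
        ids = set(insurant_ids)
        kw = {
            name: df[df["insurant_id"].isin(ids)].reset_index(drop=True)
            for name, df in self.tables().items()
        }
        return replace(self, **kw)


def _coerce_dates(df: pd.DataFrame, table: str, cols: list[str]) -> None:
    for col in cols:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.len() > 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ClaimsDataError(
                f"{table} row {i}: unparsable date {raw.iloc[i]!r} in column {col!r}"
            )
        df[col] = parsed

def _read_table(dir_path: Path, table: str) -> pd.DataFrame:
    path = dir_path / TABLE_FILES[table]
    if not path.exists():
        if table == "ancillary":
            return _empty("ancillary").assign(
                cost=pd.Series(dtype=float), service_date=pd.Series(dtype="datetime64[ns]")
            )
        raise ClaimsDataError(f"missing claims table {TABLE_FILES[table]!r} in {dir_path}")
    df = pd.read_csv(path, dtype={"insurant_id": str}, keep_default_na=True)
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise ClaimsDataError(f"{table}: missing columns {missing}")
    _coerce_dates(df, table, DATE_COLUMNS.get(table, []))
    if table == "insurants":
        df["birth_year"] = df["birth_year"].astype(int)
    if table == "diagnoses" or table == "outpatient_contacts":
        df["quarter"] = df["quarter"].astype(str)
    if table == "outpatient_contacts":
        df["n_contacts"] = df["n_contacts"].astype(int)
        df["prescriber_of_aed"] = df["prescriber_of_aed"].astype(bool)
        df["cost"] = df["cost"].astype(float)
    if table == "dispensations":
        df["cost"] = df["cost"].astype(float)
    if table == "admissions":
        df["drg_cost"] = df["drg_cost"].astype(float)
        for col in ("secondary_icds", "ops_codes"):
            df[col] = df[col].fillna("").astype(str)
    if table == "ancillary" and len(df):
        df["cost"] = df["cost"].astype(float)
    return df[TABLE_COLUMNS[table]]


def load_claims(dir_path, strict: bool = True) -> ClaimsDatabase:
    """Read a claims database from a directory of CSV tables.

    With ``strict`` (default) the database is validated after loading and the
    first violations are raised as a :class:`ClaimsDataError`.
    """
    dir_path = Path(dir_path)
    meta_path = dir_path / "metadata.json"
    if not meta_path.exists():
        raise ClaimsDataError(f"missing metadata.json in {dir_path}")
    meta = json.loads(meta_path.read_text())
    db = ClaimsDatabase(
        insurants=_read_table(dir_path, "insurants"),
        diagnoses=_read_table(dir_path, "diagnoses"),
        dispensations=_read_table(dir_path, "dispensations"),
        admissions=_read_table(dir_path, "admissions"),
        outpatient_contacts=_read_table(dir_path, "outpatient_contacts"),
        ancillary=_read_table(dir_path, "ancillary"),
        observation_start=date.fromisoformat(meta["observation_start"]),
        observation_end=date.fromisoformat(meta["observation_end"]),
    )
    if strict:
        violations = validate(db)
        if violations:
            head = "; ".join(str(v) for v in violations[:5])
            raise ClaimsDataError(
                f"claims database failed validation ({len(violations)} violations): {head}"
            )
    return db


def write_claims(db: ClaimsDatabase, dir_path) -> Path:
    """Write all tables as UTF-8 CSV plus metadata.json; round-trips exactly."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for name, df in db.tables().items():
        out = df.copy()
        for col in DATE_COLUMNS.get(name, []):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(dir_path / TABLE_FILES[name], index=False)
    (dir_path / "metadata.json").write_text(
        json.dumps(
            {
                "observation_start": db.observation_start.isoformat(),
                "observation_end": db.observation_end.isoformat(),
            },
            indent=2,
        )
    )
    return dir_path


def _in_window(series: pd.Series, start: date, end: date) -> pd.Series:
    s = pd.to_datetime(series)
    return (s >= pd.Timestamp(start)) & (s <= pd.Timestamp(end))


def validate(db: ClaimsDatabase) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions."""
    v: list[Violation] = []
    start, end = db.observation_start, db.observation_end
    known_ids = set(db.insurants["insurant_id"])

    ins = db.insurants
    if len(ins):
        dup = ins["insurant_id"].duplicated()
        for i in np.flatnonzero(dup.to_numpy()):
            v.append(Violation("insurants", int(i), "unique insurant_id"))
        bad = ~ins["sex"].isin(SEXES)
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("insurants", int(i), "sex in {female,male}", str(ins["sex"].iloc[i])))
        es, ee = pd.to_datetime(ins["enroll_start"]), pd.to_datetime(ins["enroll_end"])
        for i in np.flatnonzero((es > ee).to_numpy()):
            v.append(Violation("insurants", int(i), "enroll_start≤enroll_end"))
        dd = pd.to_datetime(ins["death_date"])
        bad = dd.notna() & ((dd < es) | (dd > ee))
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("insurants", int(i), "death within enrollment"))
        bad = ins["birth_year"] > es.dt.year
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("insurants", int(i), "birth_year≤year(enroll_start)"))

    def check_fk(name: str, df: pd.DataFrame) -> None:
        orphan = ~df["insurant_id"].isin(known_ids)
        for i in np.flatnonzero(orphan.to_numpy()):
            v.append(Violation(name, int(i), "foreign key", str(df["insurant_id"].iloc[i])))

    dx = db.diagnoses
    if len(dx):
        check_fk("diagnoses", dx)
        bad = ~dx["icd_code"].astype(str).str.match(ICD_RE)
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("diagnoses", int(i), "ICD pattern", str(dx["icd_code"].iloc[i])))
        for i, q in enumerate(dx["quarter"]):
            try:
                year, n = parse_quarter(q)
            except ClaimsDataError:
                v.append(Violation("diagnoses", i, "quarter format", str(q)))
                continue
            if not (quarter_of_date(start) <= q <= quarter_of_date(end)):
                v.append(Violation("diagnoses", i, "quarter within observation window", q))
        bad = ~dx["setting"].isin(SETTINGS)
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("diagnoses", int(i), "setting", str(dx["setting"].iloc[i])))
        bad = ~dx["position"].isin(POSITIONS)
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("diagnoses", int(i), "position", str(dx["position"].iloc[i])))

    rx = db.dispensations
    if len(rx):
        check_fk("dispensations", rx)
        atc = rx["atc_code"].astype(str)
        bad = (atc.str.len() != 7) | (atc != atc.str.upper())
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("dispensations", int(i), "ATC uppercase length 7", atc.iloc[i]))
        bad = ~_in_window(rx["dispense_date"], start, end)
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(
                Violation(
                    "dispensations", int(i), "dispense_date within observation window",
                    str(rx["dispense_date"].iloc[i].date()),
                )
            )
        for i in np.flatnonzero((rx["cost"] < 0).to_numpy()):
            v.append(Violation("dispensations", int(i), "cost≥0"))

    adm = db.admissions
    if len(adm):
        check_fk("admissions", adm)
        a, d = pd.to_datetime(adm["admit_date"]), pd.to_datetime(adm["discharge_date"])
        for i in np.flatnonzero((a > d).to_numpy()):
            v.append(Violation("admissions", int(i), "admit≤discharge"))
        for i in np.flatnonzero((adm["drg_cost"] < 0).to_numpy()):
            v.append(Violation("admissions", int(i), "drg_cost≥0"))
        bad = ~_in_window(adm["admit_date"], start, end)
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("admissions", int(i), "admit_date within observation window"))

    oc = db.outpatient_contacts
    if len(oc):
        check_fk("outpatient_contacts", oc)
        for i in np.flatnonzero((oc["n_contacts"] < 1).to_numpy()):
            v.append(Violation("outpatient_contacts", int(i), "n_contacts≥1"))
        for i in np.flatnonzero((oc["cost"] < 0).to_numpy()):
            v.append(Violation("outpatient_contacts", int(i), "cost≥0"))
        bad = ~oc["specialty"].isin(SPECIALTIES)
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("outpatient_contacts", int(i), "specialty", str(oc["specialty"].iloc[i])))

    anc = db.ancillary
    if len(anc):
        check_fk("ancillary", anc)
        for i in np.flatnonzero((anc["cost"] < 0).to_numpy()):
            v.append(Violation("ancillary", int(i), "cost≥0"))
        bad = ~anc["category"].isin(ANCILLARY_CATEGORIES)
        for i in np.flatnonzero(bad.to_numpy()):
            v.append(Violation("ancillary", int(i), "category", str(anc["category"].iloc[i])))

    return v


def length_of_stay(admit: date, discharge: date) -> int:
    """Days in hospital, counting both admission and discharge day.

    Same-day admissions count as one day, matching German per-case billing.
    """
    return (discharge - admit).days + 1
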