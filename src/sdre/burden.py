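"""Descriptive burden outcomes over index-anchored cohort time.

Every metric is computed per period, where a period is one of:

* ``baseline`` — the 365 days before the (pseudo-)index date,
* ``fu1``..``fu3`` — three consecutive 365-day follow-up years from index,
* ``fu_total`` — the union of the three follow-up years.

Cohorts are passed as a mapping insurant_id -> anchor date (a case's index
date or a control's pseudo-index). Denominators follow a single policy: a
person is at risk in a period iff alive and enrolled at the period start;
numerators and denominators are reported alongside every proportion so that
alternative conventions can be recomputed.

Day-dated events (admissions, dispensations, ancillary items) are assigned to
the period containing their date; admissions are assigned by admit date and
never split across a period boundary. Quarter-billed records (outpatient
diagnoses and physician contacts) are assigned by the quarter's midpoint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .claims_model import ClaimsDatabase, quarter_midpoint
from .stats import TwoByTwo, chi_square_2x2

__all__ = [
    "CodeSet",
    "CostSummary",
    "PERIODS",
    "ALL_PERIODS",
    "period_bounds",
    "person_period",
    "at_risk_table",
    "hospitalization_summary",
    "procedure_uptake",
    "status_epilepticus_hospitalized",
    "prescription_pattern",
    "contact_summary",
    "prevalence_compare",
    "cost_summary",
    "default_code_sets",
    "load_code_sets",
]

PERIODS = ("baseline", "fu1", "fu2", "fu3")
ALL_PERIODS = PERIODS + ("fu_total",)

YEAR = 365  # days per cohort year

_RANGE_RE = re.compile(r"^([A-Z])(\d{2})[–-]([A-Z])(\d{2})$")

EPILEPSY_PRIMARY_PREFIXES = ("G40", "G41")

COST_COMPONENTS = ("inpatient", "medication", "outpatient", "ancillary", "equipment", "dialysis")

# calendar-year periods for the calendar cost mode (the billing years the
# study reported costs for)
CALENDAR_PERIOD_YEARS = {"baseline": 2010, "fu1": 2011, "fu2": 2012, "fu3": 2013}


@dataclass(frozen=True)
class CodeSet:
    """Named set of ICD-10 prefixes and/or ranges like ``S00–S09``.

    Ranges match on the three-character category (letter + two digits); plain
    entries match as prefixes, so ``F06`` matches ``F06.2``.
    """

    name: str
    codes: tuple[str, ...]
    setting: str = "any"  # 'any' | 'inpatient_primary'

    def __post_init__(self) -> None:
        for c in self.codes:
            m = _RANGE_RE.match(c)
            if m and (m.group(1) != m.group(3) or int(m.group(2)) > int(m.group(4))):
                raise ValueError(f"malformed ICD range {c!r}")

    def matches(self, icd_codes: pd.Series) -> pd.Series:
        codes = icd_codes.astype(str).str.upper()
        mask = pd.Series(False, index=codes.index)
        cat = codes.str[:3]
        for c in self.codes:
            m = _RANGE_RE.match(c)
            if m:
                letter, lo, hi = m.group(1), int(m.group(2)), int(m.group(4))
                num = pd.to_numeric(cat.str[1:], errors="coerce")
                mask |= (cat.str[0] == letter) & (num >= lo) & (num <= hi)
            else:
                mask |= codes.str.startswith(c.upper())
        return mask


@dataclass(frozen=True)
class CostSummary:
    """Per-period direct costs (EUR, rounded to the cent per component)."""

    period: str
    inpatient: float
    medication: float
    outpatient: float
    ancillary: float
    equipment: float
    dialysis: float
    epilepsy_specific_inpatient: float
    n_at_risk: int

    @property
    def total(self) -> float:
        cents = sum(
            round(getattr(self, c) * 100)
            for c in COST_COMPONENTS
        )
        return cents / 100

    @property
    def mean_total_per_person(self) -> float:
        return self.total / self.n_at_risk if self.n_at_risk else float("nan")


def period_bounds(anchor: date, period: str) -> tuple[date, date]:
    """Half-open [start, end) interval of a period relative to its anchor."""
    if period == "baseline":
        return anchor - timedelta(days=YEAR), anchor
    if period == "fu_total":
        return anchor, anchor + timedelta(days=3 * YEAR)
    if period in ("fu1", "fu2", "fu3"):
        y = int(period[2])
        return anchor + timedelta(days=YEAR * (y - 1)), anchor + timedelta(days=YEAR * y)
    raise ValueError(f"unknown period {period!r}")


def person_period(
    enroll_start: date,
    enroll_end: date,
    death_date: date | None,
    interval: tuple[date, date],
) -> tuple[bool, int]:
    """At-risk flag and exposure days of one person in one interval.

    At risk iff enrolled and alive at the interval start; exposure runs to
    the earliest of interval end, disenrollment, and the day after death.
    """
    start, end = interval
    if not (enroll_start <= start <= enroll_end):
        return False, 0
    if death_date is not None and death_date < start:
        return False, 0
    stop = end
    stop = min(stop, enroll_end + timedelta(days=1))
    if death_date is not None:
        stop = min(stop, death_date + timedelta(days=1))
    return True, max(0, (stop - start).days)


def _anchor_frame(anchors: Mapping[str, date]) -> pd.DataFrame:
    return pd.DataFrame(
        {"insurant_id": list(anchors.keys()), "anchor": pd.to_datetime(list(anchors.values()))}
    )


def at_risk_table(
    db: ClaimsDatabase, anchors: Mapping[str, date], period: str
) -> pd.DataFrame:
    """Per-person interval plus at-risk flag and exposure days for a period.

    Columns: insurant_id, start, end, at_risk, exposure_days.
    """
    af = _anchor_frame(anchors)
    if period == "baseline":
        af["start"] = af["anchor"] - pd.Timedelta(days=YEAR)
        af["end"] = af["anchor"]
    elif period == "fu_total":
        af["start"] = af["anchor"]
        af["end"] = af["anchor"] + pd.Timedelta(days=3 * YEAR)
    else:
        y = int(period[2])
        af["start"] = af["anchor"] + pd.Timedelta(days=YEAR * (y - 1))
        af["end"] = af["anchor"] + pd.Timedelta(days=YEAR * y)

    ins = db.insurants[["insurant_id", "enroll_start", "enroll_end", "death_date"]].copy()
    for c in ("enroll_start", "enroll_end", "death_date"):
        ins[c] = pd.to_datetime(ins[c])
    m = af.merge(ins, on="insurant_id", how="left", validate="one_to_one")

    enrolled = (m["enroll_start"] <= m["start"]) & (m["start"] <= m["enroll_end"])
    alive = m["death_date"].isna() | (m["death_date"] >= m["start"])
    m["at_risk"] = enrolled & alive

    stop = m[["end"]].copy()
    stop["end"] = np.minimum(m["end"], m["enroll_end"] + pd.Timedelta(days=1))
    death_stop = m["death_date"] + pd.Timedelta(days=1)
    stop["end"] = np.where(
        m["death_date"].notna(), np.minimum(stop["end"], death_stop), stop["end"]
    )
    days = (pd.to_datetime(stop["end"]) - m["start"]).dt.days.clip(lower=0)
    m["exposure_days"] = np.where(m["at_risk"], days, 0)
    return m[["insurant_id", "start", "end", "at_risk", "exposure_days"]]


def _events_in_period(
    events: pd.DataFrame, date_col: str, risk: pd.DataFrame
) -> pd.DataFrame:
    """Events of at-risk persons whose date falls inside their interval."""
    r = risk[risk["at_risk"]][["insurant_id", "start", "end"]]
    e = events.merge(r, on="insurant_id", how="inner")
    d = pd.to_datetime(e[date_col])
    return e[(d >= e["start"]) & (d < e["end"])]


def _row(cohort, period, metric, num, den, value, dispersion=np.nan):
    return {
        "cohort": cohort,
        "period": period,
        "metric": metric,
        "numerator": num,
        "denominator": den,
        "value": value,
        "dispersion": dispersion,
    }


def hospitalization_summary(
    db: ClaimsDatabase,
    anchors: Mapping[str, date],
    periods: Iterable[str] = ALL_PERIODS,
    epilepsy_specific: bool = False,
    cohort: str = "sdre",
    primary_prefixes: tuple[str, ...] = EPILEPSY_PRIMARY_PREFIXES,
) -> pd.DataFrame:
    """Admission burden per period.

    Metrics per period: share of at-risk persons with >=1 admission, total
    admissions, mean admissions per admitted person, total hospital days
    (admission and discharge day both count), and mean stay per admission.
    With ``epilepsy_specific`` only admissions whose primary diagnosis starts
    with G40/G41 are counted.
    """
    adm = db.admissions
    if epilepsy_specific:
        p = adm["primary_icd"].astype(str).str.upper()
        adm = adm[np.logical_or.reduce([p.str.startswith(x) for x in primary_prefixes])]
    rows = []
    for period in periods:
        risk = at_risk_table(db, anchors, period)
        n_risk = int(risk["at_risk"].sum())
        ev = _events_in_period(adm, "admit_date", risk)
        label = "epilepsy_" if epilepsy_specific else ""
        n_admitted = ev["insurant_id"].nunique()
        n_adm = len(ev)
        days = (
            (pd.to_datetime(ev["discharge_date"]) - pd.to_datetime(ev["admit_date"])).dt.days + 1
        ).sum()
        rows.append(
            _row(cohort, period, f"{label}hospitalized_share", n_admitted, n_risk,
                 n_admitted / n_risk if n_risk else np.nan)
        )
        rows.append(_row(cohort, period, f"{label}total_admissions", n_adm, n_risk, n_adm))
        rows.append(
            _row(cohort, period, f"{label}mean_admissions_per_admitted", n_adm, n_admitted,
                 n_adm / n_admitted if n_admitted else np.nan)
        )
        rows.append(_row(cohort, period, f"{label}total_hospital_days", int(days), n_risk, int(days)))
        rows.append(
            _row(cohort, period, f"{label}mean_stay_per_admission", int(days), n_adm,
                 days / n_adm if n_adm else np.nan)
        )
    return pd.DataFrame(rows)


def procedure_uptake(
    db: ClaimsDatabase,
    anchors: Mapping[str, date],
    ops_prefixes: Iterable[str],
    periods: Iterable[str] = ("fu1", "fu2", "fu3", "fu_total"),
    cohort: str = "sdre",
) -> pd.DataFrame:
    """Share of the cohort with >=1 admission carrying an OPS code with each
    prefix, per period and over the whole follow-up."""
    adm = db.admissions
    rows = []
    for prefix in ops_prefixes:
        if not re.match(r"^[0-9]-\d{3}(\.\w+)?$", prefix):
            raise ValueError(f"malformed OPS prefix {prefix!r}")
        has = adm["ops_codes"].astype(str).apply(
            lambda s: any(code.strip().startswith(prefix) for code in s.split(";") if code)
        )
        sub = adm[has]
        for period in periods:
            risk = at_risk_table(db, anchors, period)
            n_risk = int(risk["at_risk"].sum())
            ev = _events_in_period(sub, "admit_date", risk)
            k = ev["insurant_id"].nunique()
            rows.append(
                _row(cohort, period, f"ops_{prefix}_share", k, n_risk,
                     k / n_risk if n_risk else np.nan)
            )
    return pd.DataFrame(rows)


def status_epilepticus_hospitalized(
    db: ClaimsDatabase, anchors: Mapping[str, date], cohort: str = "sdre"
) -> tuple[int, int, float]:
    """Patients with >=1 admission whose primary diagnosis starts G41 during
    the three follow-up years: (count, at-risk denominator, proportion)."""
    adm = db.admissions
    sub = adm[adm["primary_icd"].astype(str).str.upper().str.startswith("G41")]
    risk = at_risk_table(db, anchors, "fu_total")
    n_risk = int(risk["at_risk"].sum())
    ev = _events_in_period(sub, "admit_date", risk)
    k = ev["insurant_id"].nunique()
    return k, n_risk, (k / n_risk if n_risk else float("nan"))


def prescription_pattern(
    db: ClaimsDatabase,
    anchors: Mapping[str, date],
    periods: Iterable[str] = ALL_PERIODS,
    atc_prefix: str = "N03A",
    cohort: str = "sdre",
) -> tuple[pd.DataFrame, dict]:
    """Per-substance period shares plus distinct-substance statistics.

    Returns (shares frame, stats dict). Shares count a patient once per
    period per substance regardless of pack count. The stats dict carries the
    mean and SD of the number of distinct prefix-matching substances each
    at-risk patient received over the whole follow-up.
    """
    rx = db.dispensations
    rx = rx[rx["atc_code"].astype(str).str.upper().str.startswith(atc_prefix.upper())]
    rows = []
    for period in periods:
        risk = at_risk_table(db, anchors, period)
        n_risk = int(risk["at_risk"].sum())
        ev = _events_in_period(rx, "dispense_date", risk)
        per_sub = ev.groupby("atc_code")["insurant_id"].nunique()
        for code, k in per_sub.items():
            rows.append(
                _row(cohort, period, f"substance_share_{code}", int(k), n_risk,
                     k / n_risk if n_risk else np.nan)
            )
    risk = at_risk_table(db, anchors, "fu_total")
    ev = _events_in_period(rx, "dispense_date", risk)
    counts = ev.groupby("insurant_id")["atc_code"].nunique()
    at_risk_ids = risk.loc[risk["at_risk"], "insurant_id"]
    counts = counts.reindex(at_risk_ids).fillna(0)
    stats = {
        "distinct_aeds_fu_mean": float(counts.mean()) if len(counts) else float("nan"),
        "distinct_aeds_fu_sd": float(counts.std(ddof=1)) if len(counts) > 1 else float("nan"),
        "n": int(len(counts)),
    }
    return pd.DataFrame(rows), stats


def contact_summary(
    db: ClaimsDatabase,
    anchors: Mapping[str, date],
    periods: Iterable[str] = ALL_PERIODS,
    cohort: str = "sdre",
) -> pd.DataFrame:
    """Outpatient physician contacts per specialty and period.

    Per specialty: share of the cohort with >=1 contact, mean contacts among
    those, and share whose anticonvulsant prescriber is that specialty; plus
    the overall mean contacts per at-risk person.
    """
    oc = db.outpatient_contacts.copy()
    if len(oc):
        oc["qdate"] = pd.to_datetime([quarter_midpoint(q) for q in oc["quarter"]])
    else:
        oc["qdate"] = pd.Series(dtype="datetime64[ns]")
    rows = []
    for period in periods:
        risk = at_risk_table(db, anchors, period)
        n_risk = int(risk["at_risk"].sum())
        ev = _events_in_period(oc, "qdate", risk)
        years = 3.0 if period == "fu_total" else 1.0
        total_contacts = int(ev["n_contacts"].sum())
        rows.append(
            _row(cohort, period, "contacts_per_person_year", total_contacts, n_risk,
                 total_contacts / (n_risk * years) if n_risk else np.nan)
        )
        for spec, grp in ev.groupby("specialty"):
            per_person = grp.groupby("insurant_id")["n_contacts"].sum()
            k = len(per_person)
            rows.append(
                _row(cohort, period, f"contact_share_{spec}", k, n_risk,
                     k / n_risk if n_risk else np.nan)
            )
            rows.append(
                _row(cohort, period, f"contacts_mean_{spec}", int(per_person.sum()), k,
                     per_person.sum() / (k * years) if k else np.nan)
            )
            presc = grp.loc[grp["prescriber_of_aed"], "insurant_id"].nunique()
            rows.append(
                _row(cohort, period, f"aed_prescriber_share_{spec}", int(presc), n_risk,
                     presc / n_risk if n_risk else np.nan)
            )
    return pd.DataFrame(rows)


def prevalence_compare(
    db: ClaimsDatabase,
    case_anchors: Mapping[str, date],
    control_anchors: Mapping[str, date],
    code_set: CodeSet,
    period: str = "fu1",
) -> dict:
    """Diagnosis prevalence in cases vs controls over one period, with a
    Pearson chi-square comparison.

    A person counts once if any diagnosis in the period falls in the code
    set (prefix or three-character range match); quarterly records are
    assigned by quarter midpoint, inpatient diagnoses by admission date
    through the diagnoses table they are mirrored into.
    """
    dx = db.diagnoses.copy()
    if code_set.setting == "inpatient_primary":
        dx = dx[(dx["setting"] == "inpatient") & (dx["position"] == "primary")]
    dx = dx[code_set.matches(dx["icd_code"])]
    if len(dx):
        dx["qdate"] = pd.to_datetime([quarter_midpoint(q) for q in dx["quarter"]])
    else:
        dx["qdate"] = pd.Series(dtype="datetime64[ns]")

    out = {"code_set": code_set.name, "period": period}
    counts = {}
    for label, anchors in (("case", case_anchors), ("control", control_anchors)):
        risk = at_risk_table(db, anchors, period)
        n_risk = int(risk["at_risk"].sum())
        ev = _events_in_period(dx, "qdate", risk)
        k = ev["insurant_id"].nunique()
        counts[label] = (k, n_risk)
        out[f"p_{label}"] = k / n_risk if n_risk else float("nan")
        out[f"n_{label}"] = n_risk
        out[f"k_{label}"] = k
    (k1, n1), (k2, n2) = counts["case"], counts["control"]
    try:
        stat, _, p = chi_square_2x2(TwoByTwo.from_proportions(k1, n1, k2, n2))
    except ValueError:
        stat, p = float("nan"), float("nan")
    out["chi2"] = stat
    out["p_value"] = p
    return out


def _calendar_interval(period: str) -> tuple[date, date]:
    year = CALENDAR_PERIOD_YEARS[period]
    return date(year, 1, 1), date(year + 1, 1, 1)


def cost_summary(
    db: ClaimsDatabase,
    anchors: Mapping[str, date],
    periods: Iterable[str] = ALL_PERIODS,
    mode: str = "index_anchored",
    cohort: str = "sdre",
) -> list[CostSummary]:
    """Direct costs per period by component.

    ``index_anchored`` uses the per-person cohort years; ``calendar`` uses
    the billing calendar years instead (baseline 2010, follow-up 2011-2013;
    fu_total is their union). Inpatient costs with a G40/G41 primary
    diagnosis are additionally reported as epilepsy-specific.
    """
    if mode not in ("index_anchored", "calendar"):
        raise ValueError(f"unknown cost mode {mode!r}")
    if (db.admissions["drg_cost"] < 0).any():
        raise ValueError("negative drg_cost in admissions")

    oc = db.outpatient_contacts.copy()
    if len(oc):
        oc["qdate"] = pd.to_datetime([quarter_midpoint(q) for q in oc["quarter"]])
    else:
        oc["qdate"] = pd.Series(dtype="datetime64[ns]")

    summaries = []
    for period in periods:
        risk = at_risk_table(db, anchors, period)
        if mode == "calendar":
            if period == "fu_total":
                start, end = _calendar_interval("fu1")[0], _calendar_interval("fu3")[1]
            else:
                start, end = _calendar_interval(period)
            risk = risk.copy()
            risk["start"] = pd.Timestamp(start)
            risk["end"] = pd.Timestamp(end)
        n_risk = int(risk["at_risk"].sum())

        adm = _events_in_period(db.admissions, "admit_date", risk)
        inpatient = adm["drg_cost"].sum()
        epi = adm[
            adm["primary_icd"].astype(str).str.upper().str.startswith(EPILEPSY_PRIMARY_PREFIXES)
        ]["drg_cost"].sum()
        rx = _events_in_period(db.dispensations, "dispense_date", risk)
        medication = rx["cost"].sum()
        contacts = _events_in_period(oc, "qdate", risk)
        outpatient = contacts["cost"].sum()
        anc_events = _events_in_period(db.ancillary, "service_date", risk) if len(db.ancillary) else db.ancillary
        parts = {c: 0.0 for c in ("ancillary", "equipment", "dialysis")}
        if len(anc_events):
            for cat, grp in anc_events.groupby("category"):
                parts[cat] = grp["cost"].sum()

        summaries.append(
            CostSummary(
                period=period,
                inpatient=round(float(inpatient), 2),
                medication=round(float(medication), 2),
                outpatient=round(float(outpatient), 2),
                ancillary=round(float(parts["ancillary"]), 2),
                equipment=round(float(parts["equipment"]), 2),
                dialysis=round(float(parts["dialysis"]), 2),
                epilepsy_specific_inpatient=round(float(epi), 2),
                n_at_risk=n_risk,
            )
        )
    return summaries


def costs_to_frame(summaries: list[CostSummary], cohort: str = "sdre") -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"cohort": cohort, "period": s.period, "n_at_risk": s.n_at_risk}
        for c in COST_COMPONENTS:
            row[c] = getattr(s, c)
        row["epilepsy_specific_inpatient"] = s.epilepsy_specific_inpatient
        row["total"] = s.total
        row["mean_total_per_person"] = s.mean_total_per_person
        rows.append(row)
    return pd.DataFrame(rows)


def default_code_sets() -> dict[str, CodeSet]:
    """Comorbidity and injury code sets used in the report tables.

    The clinical labels map to ICD-10 blocks; where a label has no canonical
    block (depression, vascular, gastrointestinal, hypertension) the choice
    is an explicit, editable assumption.
    """
    return {
        cs.name: cs
        for cs in (
            CodeSet("depression", ("F32", "F33")),
            CodeSet("organic_mental_disorders", ("F06",)),
            CodeSet("somatoform_disorders", ("F45",)),
            CodeSet("personality_behavioral_disorders", ("F07",)),
            CodeSet("vascular_disorders", ("I60–I79", "G45")),
            CodeSet("gastrointestinal_disorders", ("K20–K93",)),
            CodeSet("hypertension", ("I10–I15",)),
            CodeSet("head_injury", ("S00–S09",)),
            CodeSet("trunk_limb_injury", ("T08–T14",)),
            CodeSet("knee_lower_leg_injury", ("S80–S89",)),
            CodeSet("ankle_foot_injury", ("S90–S99",)),
        )
    }


def load_code_sets(path) -> dict[str, CodeSet]:
    """Read code sets from a config file: one per line,
    ``name = CODE; CODE–CODE; ...`` (# comments allowed)."""
    sets = {}
    for raw in open(path, encoding="utf-8"):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        name, _, rhs = line.partition("=")
        codes = tuple(c.strip() for c in rhs.split(";") if c.strip())
        cs = CodeSet(name.strip(), codes)
        sets[cs.name] = cs
    return sets
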