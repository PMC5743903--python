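"""Programmatic cohort fixtures encoding the published aggregate counts.

The original sickness-fund database is not accessible, but the study's
printed aggregates (numbers of admitted patients, admissions, hospital days,
procedure recipients, prescription counts, comorbidity proportions) are
mutually consistent and can be encoded as a synthetic cohort whose summary
statistics reproduce them exactly. These builders construct such cohorts:
769 cases with a fixed index date and, where needed, 15,380 matched controls.

Everything here is synthetic data constructed from published counts; no real
insurance records are involved.
"""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd

from .claims_model import ClaimsDatabase, quarter_of_date

__all__ = ["results_cohort_db", "results_cost_db", "INDEX_DATE"]

INDEX_DATE = date(2010, 1, 2)

# published aggregates over the three follow-up years
N_CASES = 769
N_CONTROLS = 15_380
N_ADMITTED = 568
N_ADMISSIONS = 2_403
N_HOSPITAL_DAYS = 23_346
N_EPI_PATIENTS = 353
N_EPI_ADMISSIONS = 1_002
N_EPI_DAYS = 10_474
N_STATUS_PATIENTS = 94
N_COMPLEX_TREATMENT = 105   # OPS 8-972.*
N_VIDEO_EEG = 44            # OPS 1-210
N_INVASIVE_EEG = 5          # OPS 1-211
N_SURGERY = 31              # OPS 5-010
N_LEVETIRACETAM = 435       # >=1 dispensation during follow-up
N_DEPRESSION_CASES = 215    # ~28% in follow-up year 1
N_DEPRESSION_CONTROLS = 1_538  # 10%


def _insurants(ids: list[str], start: date, end: date) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "insurant_id": ids,
            "birth_year": [1950 + (i % 40) for i in range(len(ids))],
            "sex": ["female" if i % 2 else "male" for i in range(len(ids))],
            "enroll_start": pd.Timestamp(start),
            "enroll_end": pd.Timestamp(end),
            "death_date": pd.NaT,
        }
    )


def results_cohort_db() -> tuple[ClaimsDatabase, dict, dict]:
    """Cohort encoding the published hospitalization, procedure, prescription
    and comorbidity aggregates.

    Returns (db, case_anchors, control_anchors); every anchor is the same
    index date so that ``fu_total`` covers all constructed events.
    """
    obs_start, obs_end = date(2008, 1, 1), date(2013, 12, 31)
    case_ids = [f"C{i:04d}" for i in range(N_CASES)]
    control_ids = [f"K{i:05d}" for i in range(N_CONTROLS)]
    insurants = pd.concat(
        [_insurants(case_ids, obs_start, obs_end), _insurants(control_ids, obs_start, obs_end)],
        ignore_index=True,
    )

    # --- admissions: per-patient totals summing to the printed aggregates
    # patients 0..130 have 5 admissions, 131..567 have 4  (total 2,403)
    adm_per_patient = [5] * 131 + [4] * (N_ADMITTED - 131)
    # patients 0..295 have 3 epilepsy-primary admissions, 296..352 have 2 (1,002)
    epi_per_patient = [3] * 296 + [2] * (N_EPI_PATIENTS - 296) + [0] * (N_ADMITTED - N_EPI_PATIENTS)

    adm_rows = []
    epi_seq = 0   # running index over epilepsy admissions (for day assignment)
    oth_seq = 0   # running index over other admissions
    for p in range(N_ADMITTED):
        pid = case_ids[p]
        n_epi = epi_per_patient[p]
        n_oth = adm_per_patient[p] - n_epi
        admit = INDEX_DATE + timedelta(days=15)
        for j in range(n_epi):
            los = 11 if epi_seq < 454 else 10  # sums to 10,474 days
            if j == 0 and p < N_STATUS_PATIENTS:
                primary = "G41.0"
            else:
                primary = "G40.2"
            ops = []
            if j == 0:
                if p < N_COMPLEX_TREATMENT:
                    ops.append("8-972.0")
                if p < N_VIDEO_EEG:
                    ops.append("1-210")
                if p < N_INVASIVE_EEG:
                    ops.append("1-211")
                if p < N_SURGERY:
                    ops.append("5-010")
            adm_rows.append(
                (pid, admit, admit + timedelta(days=los - 1), primary, "", ";".join(ops), 1000.0)
            )
            epi_seq += 1
            admit += timedelta(days=65)
        for _ in range(n_oth):
            los = 10 if oth_seq < 263 else 9  # sums to 12,872 days
            adm_rows.append((pid, admit, admit + timedelta(days=los - 1), "J18.9", "", "", 1000.0))
            oth_seq += 1
            admit += timedelta(days=65)
    admissions = pd.DataFrame(
        adm_rows,
        columns=["insurant_id", "admit_date", "discharge_date", "primary_icd",
                 "secondary_icds", "ops_codes", "drg_cost"],
    )
    for c in ("admit_date", "discharge_date"):
        admissions[c] = pd.to_datetime(admissions[c])

    # --- dispensations: levetiracetam during follow-up for 435 patients
    rx_date = INDEX_DATE + timedelta(days=10)
    dispensations = pd.DataFrame(
        {
            "insurant_id": case_ids[:N_LEVETIRACETAM],
            "dispense_date": pd.Timestamp(rx_date),
            "atc_code": "N03AX14",
            "substance_name": "levetiracetam",
            "cost": 100.0,
        }
    )

    # --- diagnoses: epilepsy code for every case; depression in follow-up
    # year 1 for 215 cases and 1,538 controls
    q_index = quarter_of_date(INDEX_DATE)
    q_dep = quarter_of_date(INDEX_DATE + timedelta(days=100))
    dx_rows = [(pid, q_index, "G40.9", "outpatient", "secondary") for pid in case_ids]
    dx_rows += [
        (pid, q_dep, "F32.1", "outpatient", "secondary")
        for pid in case_ids[:N_DEPRESSION_CASES]
    ]
    dx_rows += [
        (pid, q_dep, "F32.1", "outpatient", "secondary")
        for pid in control_ids[:N_DEPRESSION_CONTROLS]
    ]
    diagnoses = pd.DataFrame(
        dx_rows, columns=["insurant_id", "quarter", "icd_code", "setting", "position"]
    )

    outpatient = pd.DataFrame(
        columns=["insurant_id", "quarter", "specialty", "n_contacts", "prescriber_of_aed", "cost"]
    ).astype({"n_contacts": int, "prescriber_of_aed": bool, "cost": float}, errors="ignore")

    db = ClaimsDatabase(
        insurants=insurants,
        diagnoses=diagnoses,
        dispensations=dispensations,
        admissions=admissions,
        outpatient_contacts=outpatient,
        observation_start=obs_start,
        observation_end=obs_end,
    )
    case_anchors = {pid: INDEX_DATE for pid in case_ids}
    control_anchors = {pid: INDEX_DATE for pid in control_ids}
    return db, case_anchors, control_anchors


def results_cost_db(n_patients: int = 100) -> tuple[ClaimsDatabase, dict]:
    """Cohort whose per-patient-year direct costs match the published cost
    structure: total ~EUR 13,800 per follow-up year with inpatient ~40% and
    medication ~35.5% of the total."""
    obs_start, obs_end = date(2008, 1, 1), date(2013, 12, 31)
    ids = [f"C{i:04d}" for i in range(n_patients)]
    insurants = _insurants(ids, obs_start, obs_end)

    adm_rows, rx_rows, oc_rows, anc_rows, dx_rows = [], [], [], [], []
    for pid in ids:
        dx_rows.append((pid, quarter_of_date(INDEX_DATE), "G40.9", "outpatient", "secondary"))
        for y in range(3):
            y_start = INDEX_DATE + timedelta(days=365 * y)
            admit = y_start + timedelta(days=40)
            adm_rows.append((pid, admit, admit + timedelta(days=9), "G40.2", "", "", 5500.0))
            rx_rows.append((pid, y_start + timedelta(days=20), "N03AX14", "levetiracetam", 4900.0))
            oc_rows.append((pid, quarter_of_date(y_start + timedelta(days=50)), "general_practitioner", 4, True, 1000.0))
            anc_rows.append((pid, y_start + timedelta(days=60), "ancillary", 1500.0))
            anc_rows.append((pid, y_start + timedelta(days=61), "equipment", 600.0))
            anc_rows.append((pid, y_start + timedelta(days=62), "dialysis", 300.0))

    admissions = pd.DataFrame(
        adm_rows,
        columns=["insurant_id", "admit_date", "discharge_date", "primary_icd",
                 "secondary_icds", "ops_codes", "drg_cost"],
    )
    for c in ("admit_date", "discharge_date"):
        admissions[c] = pd.to_datetime(admissions[c])
    dispensations = pd.DataFrame(
        rx_rows, columns=["insurant_id", "dispense_date", "atc_code", "substance_name", "cost"]
    )
    dispensations["dispense_date"] = pd.to_datetime(dispensations["dispense_date"])
    outpatient = pd.DataFrame(
        oc_rows, columns=["insurant_id", "quarter", "specialty", "n_contacts", "prescriber_of_aed", "cost"]
    )
    ancillary = pd.DataFrame(anc_rows, columns=["insurant_id", "service_date", "category", "cost"])
    ancillary["service_date"] = pd.to_datetime(ancillary["service_date"])
    diagnoses = pd.DataFrame(
        dx_rows, columns=["insurant_id", "quarter", "icd_code", "setting", "position"]
    )

    db = ClaimsDatabase(
        insurants=insurants,
        diagnoses=diagnoses,
        dispensations=dispensations,
        admissions=admissions,
        outpatient_contacts=outpatient,
        ancillary=ancillary,
        observation_start=obs_start,
        observation_end=obs_end,
    )
    return db, {pid: INDEX_DATE for pid in ids}
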