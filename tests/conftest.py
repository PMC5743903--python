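from datetime import date

import pandas as pd
import pytest

from sdre.claims_model import ClaimsDatabase
from sdre.synthetic_claims import SimulationParams, simulate_claims


def make_tiny_db() -> ClaimsDatabase:
    """Hand-written database: 3 insurants, 5 dispensations, one of everything."""
    insurants = pd.DataFrame(
        {
            "insurant_id": ["A", "B", "C"],
            "birth_year": [1970, 1985, 2001],
            "sex": ["female", "male", "female"],
            "enroll_start": pd.to_datetime(["2008-01-01"] * 3),
            "enroll_end": pd.to_datetime(["2013-12-31"] * 3),
            "death_date": pd.to_datetime([None, "2012-06-01", None]),
        }
    )
    diagnoses = pd.DataFrame(
        {
            "insurant_id": ["A", "A", "B"],
            "quarter": ["2009Q1", "2010Q3", "2011Q2"],
            "icd_code": ["G40.2", "F32.1", "I10.0"],
            "setting": ["outpatient", "outpatient", "inpatient"],
            "position": ["secondary", "secondary", "primary"],
        }
    )
    dispensations = pd.DataFrame(
        {
            "insurant_id": ["A", "A", "A", "A", "B"],
            "dispense_date": pd.to_datetime(
                ["2009-02-01", "2009-05-01", "2009-09-01", "2010-01-15", "2010-06-01"]
            ),
            "atc_code": ["N03AX14", "N03AX09", "N03AG01", "N03AX18", "M01AE01"],
            "substance_name": ["levetiracetam", "lamotrigine", "valproate", "lacosamide", "ibuprofen"],
            "cost": [410.5, 200.0, 150.25, 600.0, 12.3],
        }
    )
    admissions = pd.DataFrame(
        {
            "insurant_id": ["A", "B"],
            "admit_date": pd.to_datetime(["2010-03-01", "2011-05-10"]),
            "discharge_date": pd.to_datetime(["2010-03-10", "2011-05-10"]),
            "primary_icd": ["G40.2", "I10.0"],
            "secondary_icds": ["F32.1;I10.0", ""],
            "ops_codes": ["8-972.0", ""],
            "drg_cost": [4500.0, 2000.0],
        }
    )
    outpatient = pd.DataFrame(
        {
            "insurant_id": ["A", "C"],
            "quarter": ["2010Q1", "2012Q4"],
            "specialty": ["neurologist", "general_practitioner"],
            "n_contacts": [3, 1],
            "prescriber_of_aed": [True, False],
            "cost": [225.0, 75.0],
        }
    )
    return ClaimsDatabase(
        insurants=insurants,
        diagnoses=diagnoses,
        dispensations=dispensations,
        admissions=admissions,
        outpatient_contacts=outpatient,
        observation_start=date(2008, 1, 1),
        observation_end=date(2013, 12, 31),
    )


@pytest.fixture
def tiny_db() -> ClaimsDatabase:
    return make_tiny_db()


@pytest.fixture(scope="session")
def sim_params() -> SimulationParams:
    """Small but case-rich simulation shared across tests (~40 cases)."""
    return SimulationParams(
        n_insurants=5_000, epilepsy_prevalence=0.02, refractory_fraction=0.5, seed=3
    )


@pytest.fixture(scope="session")
def sim_db(sim_params):
    return simulate_claims(sim_params)
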