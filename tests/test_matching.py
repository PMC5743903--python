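from datetime import date

import pandas as pd
import pytest

from sdre.claims_model import ClaimsDatabase
from sdre.matching import match_controls
from sdre.phenotyping import SdreCase

SUBS = frozenset(["N03AX14", "N03AX09", "N03AG01", "N03AX18"])


def pool_db(n_per_stratum=50, birth_years=(1960, 1975), epileptic_controls=()):
    """Database with cases X<year> and ample matching pools per stratum."""
    rows = []
    dx_rows = []
    for by in birth_years:
        rows.append((f"X{by}", by, "female"))
        for i in range(n_per_stratum):
            rows.append((f"P{by}_{i:03d}", by, "female"))
        for i in range(5):
            rows.append((f"M{by}_{i:03d}", by, "male"))  # wrong sex, never eligible
    ins = pd.DataFrame(rows, columns=["insurant_id", "birth_year", "sex"])
    ins["enroll_start"] = pd.Timestamp("2008-01-01")
    ins["enroll_end"] = pd.Timestamp("2013-12-31")
    ins["death_date"] = pd.NaT
    for pid in epileptic_controls:
        dx_rows.append((pid, "2009Q2", "G40.1", "outpatient", "secondary"))
    for by in birth_years:
        dx_rows.append((f"X{by}", "2009Q1", "G40.9", "outpatient", "secondary"))
    dx = pd.DataFrame(
        dx_rows, columns=["insurant_id", "quarter", "icd_code", "setting", "position"]
    )
    empty_rx = pd.DataFrame(
        columns=["insurant_id", "dispense_date", "atc_code", "substance_name", "cost"]
    )
    empty_adm = pd.DataFrame(
        columns=["insurant_id", "admit_date", "discharge_date", "primary_icd",
                 "secondary_icds", "ops_codes", "drg_cost"]
    )
    empty_oc = pd.DataFrame(
        columns=["insurant_id", "quarter", "specialty", "n_contacts", "prescriber_of_aed", "cost"]
    )
    return ClaimsDatabase(
        insurants=ins, diagnoses=dx, dispensations=empty_rx, admissions=empty_adm,
        outpatient_contacts=empty_oc,
        observation_start=date(2008, 1, 1), observation_end=date(2013, 12, 31),
    )


def cases_for(birth_years=(1960, 1975)):
    return [SdreCase(f"X{by}", date(2010, 3, 1), SUBS) for by in birth_years]


class TestMatchControls:
    def test_full_ratio_with_ample_pool(self):
        db = pool_db()
        cohort = match_controls(db, cases_for(), ratio=20, seed=1)
        assert len(cohort.pairs) == 40
        assert cohort.shortfalls == {}
        # exact stratum match
        attrs = db.insurants.set_index("insurant_id")
        for case_id, control_id in cohort.pairs:
            assert attrs.loc[control_id, "birth_year"] == attrs.loc[case_id, "birth_year"]
            assert attrs.loc[control_id, "sex"] == attrs.loc[case_id, "sex"]

    def test_no_control_sampled_twice(self):
        db = pool_db(n_per_stratum=25, birth_years=(1960,))
        cases = [SdreCase("X1960", date(2010, 3, 1), SUBS)]
        # add a second case in the same stratum
        db.insurants.loc[len(db.insurants)] = ["X1960b", 1960, "female",
                                               pd.Timestamp("2008-01-01"), pd.Timestamp("2013-12-31"), pd.NaT]
        db.diagnoses.loc[len(db.diagnoses)] = ["X1960b", "2009Q1", "G40.9", "outpatient", "secondary"]
        cases.append(SdreCase("X1960b", date(2010, 5, 1), SUBS))
        cohort = match_controls(db, cases, ratio=20, seed=1)
        ids = cohort.control_ids
        assert len(ids) == len(set(ids))
        # 25 controls for 2 cases at ratio 20: pool exhausts, shortfall recorded
        assert sum(cohort.shortfalls.values()) == 25 - 20

    def test_epileptic_insurants_never_matched(self):
        tainted = [f"P1960_{i:03d}" for i in range(30)]
        db = pool_db(epileptic_controls=tainted)
        cohort = match_controls(db, cases_for(), ratio=20, seed=4)
        assert not set(cohort.control_ids) & set(tainted)
        prefix = db.diagnoses["icd_code"].str.startswith("G40")
        g40_ids = set(db.diagnoses.loc[prefix, "insurant_id"])
        assert not set(cohort.control_ids) & g40_ids

    def test_pseudo_index_inherited_from_case(self):
        db = pool_db()
        cohort = match_controls(db, cases_for(), ratio=5, seed=2)
        for case_id, control_id in cohort.pairs:
            assert cohort.pseudo_index[control_id] == date(2010, 3, 1)

    def test_deterministic_under_fixed_seed(self):
        db = pool_db()
        a = match_controls(db, cases_for(), ratio=20, seed=9)
        b = match_controls(db, cases_for(), ratio=20, seed=9)
        assert a.pairs == b.pairs
        c = match_controls(db, cases_for(), ratio=20, seed=10)
        assert a.pairs != c.pairs

    def test_removing_one_case_leaves_others_unchanged(self):
        db = pool_db(birth_years=(1960, 1975, 1990))
        cases = cases_for(birth_years=(1960, 1975, 1990))
        full = match_controls(db, cases, ratio=20, seed=3)
        reduced = match_controls(db, cases[1:], ratio=20, seed=3)
        for case in cases[1:]:
            assert full.controls_of(case.insurant_id) == reduced.controls_of(case.insurant_id)

    def test_control_not_enrolled_at_index_excluded(self):
        db = pool_db(n_per_stratum=10, birth_years=(1960,))
        db.insurants.loc[
            db.insurants["insurant_id"].str.startswith("P1960"), "enroll_end"
        ] = pd.Timestamp("2009-12-31")
        cohort = match_controls(db, cases_for(birth_years=(1960,)), ratio=20, seed=0)
        assert cohort.pairs == []
        assert cohort.shortfalls == {"X1960": 0}

    def test_marginal_distribution_matches_cases_times_ratio(self, sim_db):
        db, _ = sim_db
        from sdre.phenotyping import identify_sdre_cases

        cases = identify_sdre_cases(db)
        cohort = match_controls(db, cases, ratio=10, seed=5)
        attrs = db.insurants.set_index("insurant_id")
        case_strata = {}
        for c in cases:
            if c.insurant_id in {k for k, _ in cohort.pairs}:
                key = (int(attrs.loc[c.insurant_id, "birth_year"]), attrs.loc[c.insurant_id, "sex"])
                case_strata.setdefault(key, 0)
        for case_id, control_id in cohort.pairs:
            key = (int(attrs.loc[control_id, "birth_year"]), attrs.loc[control_id, "sex"])
            case_key = (int(attrs.loc[case_id, "birth_year"]), attrs.loc[case_id, "sex"])
            assert key == case_key
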