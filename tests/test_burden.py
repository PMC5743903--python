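from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from sdre.burden import (
    ALL_PERIODS,
    CodeSet,
    at_risk_table,
    contact_summary,
    cost_summary,
    default_code_sets,
    hospitalization_summary,
    load_code_sets,
    period_bounds,
    person_period,
    prescription_pattern,
    prevalence_compare,
    procedure_uptake,
)
from sdre.results_fixtures import INDEX_DATE, results_cohort_db, results_cost_db


@pytest.fixture(scope="module")
def cohort():
    return results_cohort_db()


@pytest.fixture(scope="module")
def cost_cohort():
    return results_cost_db()


class TestPersonPeriod:
    ENROLL = (date(2008, 1, 1), date(2013, 12, 31))

    def test_death_before_period_start_not_at_risk(self):
        interval = period_bounds(date(2010, 1, 1), "fu2")
        at_risk, days = person_period(*self.ENROLL, date(2010, 6, 1), interval)
        assert not at_risk and days == 0

    def test_death_mid_period_truncates_exposure(self):
        interval = period_bounds(date(2010, 1, 1), "fu1")
        at_risk, days = person_period(*self.ENROLL, date(2010, 3, 1), interval)
        assert at_risk and 0 < days < 365
        assert days == (date(2010, 3, 2) - date(2010, 1, 1)).days

    def test_survivor_fully_exposed(self):
        interval = period_bounds(date(2010, 1, 1), "fu1")
        at_risk, days = person_period(*self.ENROLL, None, interval)
        assert at_risk and days == 365

    def test_not_enrolled_at_start_not_at_risk(self):
        interval = period_bounds(date(2010, 1, 1), "baseline")
        at_risk, days = person_period(date(2009, 6, 1), self.ENROLL[1], None, interval)
        assert not at_risk and days == 0


class TestHospitalization:
    def test_reproduces_published_all_cause_aggregates(self, cohort):
        db, anchors, _ = cohort
        h = hospitalization_summary(db, anchors, periods=["fu_total"]).set_index("metric")
        assert h.loc["hospitalized_share", "numerator"] == 568
        assert h.loc["total_admissions", "numerator"] == 2403
        assert h.loc["total_hospital_days", "numerator"] == 23346
        assert round(h.loc["mean_admissions_per_admitted", "value"], 1) == 4.2
        assert round(h.loc["mean_stay_per_admission", "value"], 1) == 9.7

    def test_reproduces_published_epilepsy_specific_aggregates(self, cohort):
        db, anchors, _ = cohort
        h = hospitalization_summary(
            db, anchors, periods=["fu_total"], epilepsy_specific=True
        ).set_index("metric")
        assert h.loc["epilepsy_hospitalized_share", "numerator"] == 353
        assert h.loc["epilepsy_total_admissions", "numerator"] == 1002
        assert h.loc["epilepsy_total_hospital_days", "numerator"] == 10474
        assert round(h.loc["epilepsy_mean_admissions_per_admitted", "value"], 1) == 2.8
        assert round(h.loc["epilepsy_mean_stay_per_admission", "value"], 1) == 10.5

    def test_zero_admission_cohort_reports_null_means(self, cohort):
        db, _, control_anchors = cohort
        some = dict(list(control_anchors.items())[:50])
        h = hospitalization_summary(db, some, periods=["fu1"]).set_index("metric")
        assert h.loc["hospitalized_share", "value"] == 0
        assert np.isnan(h.loc["mean_admissions_per_admitted", "value"])
        assert np.isnan(h.loc["mean_stay_per_admission", "value"])

    def test_fu_total_counts_equal_annual_sums(self, sim_db):
        db, truth = sim_db
        f = truth.frame
        anchors = {
            r.insurant_id: date.fromisoformat(r.true_index_date)
            for r in f[f.is_refractory].itertuples()
        }
        h = hospitalization_summary(db, anchors)
        for metric in ("total_admissions", "total_hospital_days"):
            per_year = h[(h.metric == metric) & h.period.isin(["fu1", "fu2", "fu3"])]["numerator"].sum()
            total = h[(h.metric == metric) & (h.period == "fu_total")]["numerator"].iloc[0]
            assert per_year == total

    def test_matches_naive_per_patient_loop(self, sim_db):
        db, truth = sim_db
        f = truth.frame
        anchors = {
            r.insurant_id: date.fromisoformat(r.true_index_date)
            for r in f[f.is_refractory].itertuples()
        }
        h = hospitalization_summary(db, anchors, periods=["fu1"]).set_index("metric")
        ins = db.insurants.set_index("insurant_id")
        n_admitted = n_adm = n_days = n_risk = 0
        for pid, anchor in anchors.items():
            row = ins.loc[pid]
            dd = row["death_date"].date() if pd.notna(row["death_date"]) else None
            interval = period_bounds(anchor, "fu1")
            at_risk, _ = person_period(
                row["enroll_start"].date(), row["enroll_end"].date(), dd, interval
            )
            if not at_risk:
                continue
            n_risk += 1
            adm = db.admissions[db.admissions["insurant_id"] == pid]
            k = 0
            for a in adm.itertuples():
                d = a.admit_date.date()
                if interval[0] <= d < interval[1]:
                    k += 1
                    n_days += (a.discharge_date - a.admit_date).days + 1
            n_adm += k
            n_admitted += k > 0
        assert h.loc["hospitalized_share", "numerator"] == n_admitted
        assert h.loc["hospitalized_share", "denominator"] == n_risk
        assert h.loc["total_admissions", "numerator"] == n_adm
        assert h.loc["total_hospital_days", "numerator"] == n_days


class TestProceduresAndStatus:
    def test_reproduces_published_uptake(self, cohort):
        from sdre.burden import status_epilepticus_hospitalized

        db, anchors, _ = cohort
        pu = procedure_uptake(
            db, anchors, ["8-972", "1-210", "5-010", "1-211"], periods=["fu_total"]
        ).set_index("metric")
        assert round(100 * pu.loc["ops_8-972_share", "value"], 1) == 13.7  # 105/769
        assert pu.loc["ops_8-972_share", "numerator"] == 105
        assert pu.loc["ops_1-210_share", "numerator"] == 44
        assert round(100 * pu.loc["ops_1-210_share", "value"], 1) == 5.7
        assert pu.loc["ops_5-010_share", "numerator"] == 31
        assert pu.loc["ops_1-211_share", "numerator"] == 5

        k, n, prop = status_epilepticus_hospitalized(db, anchors)
        assert (k, n) == (94, 769)
        assert round(100 * prop, 1) == 12.2

    def test_malformed_prefix_fatal(self, cohort):
        db, anchors, _ = cohort
        with pytest.raises(ValueError, match="OPS"):
            procedure_uptake(db, anchors, ["banana"], periods=["fu_total"])

    def test_no_matching_codes_gives_zero(self, cohort):
        db, anchors, _ = cohort
        pu = procedure_uptake(db, anchors, ["9-999"], periods=["fu_total"])
        assert (pu["value"] == 0).all()


class TestPrescriptions:
    def test_levetiracetam_share_matches_published(self, cohort):
        db, anchors, _ = cohort
        shares, _ = prescription_pattern(db, anchors, periods=["fu_total"])
        row = shares[shares.metric == "substance_share_N03AX14"].iloc[0]
        assert row["numerator"] == 435
        assert round(100 * row["value"], 1) == 56.6

    def test_share_is_per_period(self, cohort):
        db, anchors, _ = cohort
        shares, _ = prescription_pattern(db, anchors, periods=["fu1", "fu2"])
        fu1 = shares[(shares.period == "fu1") & (shares.metric == "substance_share_N03AX14")]
        fu2 = shares[(shares.period == "fu2") & (shares.metric == "substance_share_N03AX14")]
        assert fu1.iloc[0]["numerator"] == 435  # dispensed 10 days after index
        assert len(fu2) == 0  # nothing dispensed in year 2

    def test_single_substance_each_gives_mean_one_sd_zero(self, cohort):
        db, anchors, _ = cohort
        sub = dict(list(anchors.items())[:435])  # those with the dispensation
        _, stats = prescription_pattern(db, sub, periods=["fu_total"])
        assert stats["distinct_aeds_fu_mean"] == 1.0
        assert stats["distinct_aeds_fu_sd"] == 0.0


class TestContacts:
    def test_no_contacts_all_zero(self, cohort):
        db, anchors, _ = cohort
        c = contact_summary(db, dict(list(anchors.items())[:10]), periods=["fu1"])
        row = c[c.metric == "contacts_per_person_year"].iloc[0]
        assert row["value"] == 0

    def test_uniform_gp_visit_metrics(self, cost_cohort):
        db, anchors = cost_cohort
        c = contact_summary(db, anchors, periods=["fu1"]).set_index("metric")
        assert c.loc["contact_share_general_practitioner", "value"] == 1.0
        assert c.loc["contacts_mean_general_practitioner", "value"] == 4.0
        assert c.loc["aed_prescriber_share_general_practitioner", "value"] == 1.0


class TestPrevalence:
    def test_depression_28_vs_10_percent(self, cohort):
        db, case_anchors, control_anchors = cohort
        res = prevalence_compare(
            db, case_anchors, control_anchors, default_code_sets()["depression"], "fu1"
        )
        assert res["k_case"] == 215 and res["n_case"] == 769
        assert round(100 * res["p_case"], 1) == 28.0
        assert round(100 * res["p_control"], 1) == 10.0
        # closed-form Pearson chi-square oracle
        a, b = 215, 769 - 215
        c, d = 1538, 15380 - 1538
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res["chi2"] == pytest.approx(expected, abs=1e-9)
        assert res["p_value"] < 0.001

    def test_identical_cohorts_give_zero_statistic(self, cohort):
        db, case_anchors, _ = cohort
        res = prevalence_compare(db, case_anchors, case_anchors, default_code_sets()["depression"], "fu1")
        assert res["p_case"] == res["p_control"]
        assert res["chi2"] == pytest.approx(0.0)

    def test_range_semantics(self):
        cs = CodeSet("head", ("S00–S09",))
        got = cs.matches(pd.Series(["S06.1", "S10.0", "S00", "T06.1"]))
        assert list(got) == [True, False, True, False]

    def test_malformed_range_rejected(self):
        with pytest.raises(ValueError):
            CodeSet("bad", ("S09–S00",))
        with pytest.raises(ValueError):
            CodeSet("bad", ("S00–T09",))

    def test_code_sets_config_round_trip(self, tmp_path):
        p = tmp_path / "codesets.cfg"
        p.write_text("# comment\ndepression = F32; F33\nhead_injury = S00–S09\n")
        sets = load_code_sets(p)
        assert sets["depression"].codes == ("F32", "F33")
        assert sets["head_injury"].matches(pd.Series(["S05.1"])).iloc[0]


class TestCosts:
    def test_published_cost_structure(self, cost_cohort):
        db, anchors = cost_cohort
        for s in cost_summary(db, anchors, periods=["fu1", "fu2", "fu3"]):
            per_patient = s.mean_total_per_person
            assert 12_925 <= per_patient <= 14_639
            assert 0.37 <= s.inpatient / s.total <= 0.42
            assert 0.35 <= s.medication / s.total <= 0.38

    def test_total_equals_component_sum_to_the_cent(self, sim_db):
        db, truth = sim_db
        f = truth.frame
        anchors = {
            r.insurant_id: date.fromisoformat(r.true_index_date)
            for r in f[f.is_refractory].itertuples()
        }
        for s in cost_summary(db, anchors):
            parts = s.inpatient + s.medication + s.outpatient + s.ancillary + s.equipment + s.dialysis
            assert round(parts * 100) == round(s.total * 100)

    def test_single_epilepsy_admission(self, tiny_db):
        anchors = {"A": date(2010, 1, 15)}
        s = cost_summary(tiny_db, anchors, periods=["fu1"])[0]
        assert s.inpatient == 4500.0
        assert s.epilepsy_specific_inpatient == 4500.0

    def test_empty_cohort_all_zero(self, tiny_db):
        s = cost_summary(tiny_db, {}, periods=["fu1"])[0]
        assert s.total == 0.0
        assert s.n_at_risk == 0

    def test_calendar_mode_uses_billing_years(self, cost_cohort):
        db, anchors = cost_cohort
        # index 2010-01-02: follow-up years nearly coincide with 2010-2012,
        # so calendar fu1 (2011) captures the year-2 spend
        idx_mode = cost_summary(db, anchors, periods=["fu2"])[0]
        cal_mode = cost_summary(db, anchors, periods=["fu1"], mode="calendar")[0]
        assert cal_mode.total == pytest.approx(idx_mode.total)

    def test_negative_cost_fatal(self, tiny_db):
        tiny_db.admissions.loc[0, "drg_cost"] = -5.0
        with pytest.raises(ValueError, match="negative"):
            cost_summary(tiny_db, {"A": date(2010, 1, 15)})


class TestDenominators:
    def test_deaths_shrink_later_year_denominators(self, sim_db):
        db, truth = sim_db
        f = truth.frame
        anchors = {
            r.insurant_id: date.fromisoformat(r.true_index_date)
            for r in f[f.is_refractory].itertuples()
        }
        ns = [int(at_risk_table(db, anchors, p)["at_risk"].sum()) for p in ("fu1", "fu2", "fu3")]
        assert ns[0] >= ns[1] >= ns[2]
        assert ns[0] == len(anchors)  # all enrolled and alive at index
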