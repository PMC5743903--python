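"""Seeded synthetic statutory-claims generator with known ground truth.

The generator emulates the structure of a 5% statutory-insurance research
sample observed 2008-2013: an age/sex pyramid of insurants, quarterly-billed
outpatient diagnoses and physician contacts, day-dated drug dispensations
(ATC-coded) and inpatient admissions (ICD/OPS-coded with a DRG case cost).

Defaults encode the study conditions of a severely drug-refractory epilepsy
(SDRE) cohort: epilepsy prevalence ~0.8%, a refractory subgroup that accrues
at least four distinct anticonvulsant substances (ATC N03A) within 18 months
with the fourth dispensation falling in 2009-2010, elevated hospitalization
(annual rate ~49% vs ~12% background, clustered within patients via gamma
frailty), piecewise-constant excess mortality from the index date (7.8% in
follow-up year 1, 14% cumulative over three years, vs ~2.1%/3y background),
comorbidity excess by ICD block, and lognormal cost components.

Drug histories are a per-patient process over substances: scheduled accrual
of the first four substances (latency from first to fourth drawn around 212
+/- 136 days), quarterly refills while a substance stays active, and further
substance additions at a per-quarter switch probability that is much higher
for refractory than for non-refractory patients (by default non-refractory
patients are additionally capped at 3 lifetime substances, which makes the
phenotype exactly learnable).

Same parameters + same seed => byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .claims_model import ClaimsDatabase, quarter_of_date

__all__ = ["SimulationParams", "GroundTruth", "simulate_claims", "default_params"]

# (age_lo, age_hi, sex, weight): coarse population pyramid
DEFAULT_PYRAMID = tuple(
    (lo, hi, sex, w)
    for (lo, hi, w) in (
        (0, 9, 0.043),
        (10, 19, 0.050),
        (20, 29, 0.060),
        (30, 39, 0.061),
        (40, 49, 0.082),
        (50, 59, 0.070),
        (60, 69, 0.056),
        (70, 79, 0.047),
        (80, 89, 0.026),
        (90, 99, 0.005),
    )
    for sex in ("female", "male")
)

DEFAULT_AED_POOL = (
    "N03AX14",  # levetiracetam
    "N03AX09",  # lamotrigine
    "N03AG01",  # valproate
    "N03AX18",  # lacosamide
    "N03AX11",  # topiramate
    "N03AF01",  # carbamazepine
    "N03AF02",  # oxcarbazepine
    "N03AX12",  # gabapentin
    "N03AX16",  # pregabalin
    "N03AB02",  # phenytoin
    "N03AE01",  # clonazepam
    "N03AX17",  # stiripentol
    "N03AX22",  # perampanel
    "N03AA02",  # phenobarbital
)

# comorbidity blocks: (representative ICD code, annual case prob, annual control prob)
DEFAULT_COMORBIDITY = (
    ("F32.1", 0.28, 0.10),   # depression
    ("F06.7", 0.248, 0.05),  # organic mental disorders
    ("F45.0", 0.208, 0.08),  # somatoform disorders
    ("F07.0", 0.196, 0.02),  # personality/behavioral disorders
    ("I63.9", 0.22, 0.05),   # vascular disorders / stroke
    ("K29.1", 0.26, 0.13),   # gastrointestinal
    ("I10.0", 0.30, 0.30),   # hypertension (no excess)
    ("S06.0", 0.16, 0.03),   # head injury
    ("T11.0", 0.16, 0.08),   # trunk/limb injury
    ("S82.0", 0.06, 0.03),   # knee / lower leg injury
    ("S93.4", 0.05, 0.03),   # ankle / foot injury
)

# non-epilepsy primary diagnoses for background admissions; disjoint from the
# tracked comorbidity blocks so prevalences stay at their configured rates
_BACKGROUND_PRIMARY = ("M54.4", "J18.9", "E11.9", "N39.0", "J44.1", "M17.1", "A09.0")
# secondary inpatient diagnoses, likewise outside the tracked blocks
_SECONDARY_POOL = ("E11.9", "M54.4", "J45.9", "N39.0", "H52.1", "E78.0")

# per-specialty contact process: (P(any contact in a year), mean contacts/year)
DEFAULT_CONTACTS_CASE = {
    "general_practitioner": (0.95, 4.95),
    "neurologist": (0.30, 2.95),
    "neuropsychiatrist": (0.40, 3.45),
    "neuropediatrician": (0.031, 2.15),
    "radiologist": (0.21, 1.30),
    "other": (0.90, 5.00),
}
DEFAULT_CONTACTS_CONTROL = {
    "general_practitioner": (0.85, 3.50),
    "neurologist": (0.04, 1.50),
    "neuropsychiatrist": (0.05, 1.50),
    "neuropediatrician": (0.01, 1.50),
    "radiologist": (0.12, 1.20),
    "other": (0.60, 2.50),
}
# share of case person-years in which each specialty prescribes the AEDs
DEFAULT_PRESCRIBER_SHARE = {
    "general_practitioner": 0.55,
    "neurologist": 0.245,
    "neuropsychiatrist": 0.355,
}


@dataclass(frozen=True)
class SimulationParams:
    n_insurants: int = 20_000
    observation_start: date = date(2008, 1, 1)
    observation_end: date = date(2013, 12, 31)
    identification_start: date = date(2009, 1, 1)
    identification_end: date = date(2010, 12, 31)
    pyramid: tuple = DEFAULT_PYRAMID
    epilepsy_prevalence: float = 0.008
    refractory_fraction: float = 0.10
    aed_substance_pool: tuple = DEFAULT_AED_POOL
    # drug process
    switch_prob_refractory: float = 0.20   # per-quarter new-substance prob after index
    switch_prob_nonrefractory: float = 0.04
    nonrefractory_substance_cap: int | None = 3
    latency_mean_days: float = 212.0       # first to fourth substance
    latency_sd_days: float = 136.2
    window_days: int = 548
    substance_active_quarters_mean: float = 7.0
    # admissions (gamma-Poisson: annual count ~ Poisson(frailty * mu))
    admission_mu_cases: float = 1.04
    admission_shape_cases: float = 0.8
    admission_mu_controls: float = 0.183
    admission_shape_controls: float = 0.19
    epilepsy_admission_fraction: float = 0.417
    status_epilepticus_fraction: float = 0.10  # of epilepsy-primary admissions
    los_mean_cases: float = 9.7
    los_mean_controls: float = 7.5
    los_sigma: float = 0.9
    # procedure probabilities per epilepsy-primary admission
    ops_complex_prob: float = 0.15    # 8-972.*
    ops_video_eeg_prob: float = 0.05  # 1-210
    ops_surgery_prob: float = 0.03    # 5-010
    # mortality
    case_first_year_risk: float = 0.078
    case_three_year_risk: float = 0.14
    background_annual_hazard: float = 0.007073  # => ~2.1% over 3 years
    # comorbidity and contacts
    comorbidity: tuple = DEFAULT_COMORBIDITY
    gp_diagnosis_prob: float = 0.6  # quarterly epilepsy-code billing prob for cases
    contacts_case: dict = field(default_factory=lambda: dict(DEFAULT_CONTACTS_CASE))
    contacts_control: dict = field(default_factory=lambda: dict(DEFAULT_CONTACTS_CONTROL))
    prescriber_share: dict = field(default_factory=lambda: dict(DEFAULT_PRESCRIBER_SHARE))
    contact_cost_eur: float = 75.0
    # costs (lognormal with given mean; sigma on log scale)
    drg_cost_mean_cases: float = 5300.0
    drg_cost_mean_controls: float = 3000.0
    drg_cost_sigma: float = 0.8
    aed_cost_mean: float = 410.0
    aed_cost_sigma: float = 0.5
    background_rx_rate: float = 2.0     # non-AED dispensations / person-year
    background_rx_cost_mean: float = 30.0
    # ancillary items: (category, P(any in a case-year), mean EUR, control multiplier)
    ancillary_spec: tuple = (
        ("ancillary", 0.60, 1800.0, 0.25),
        ("equipment", 0.20, 2000.0, 0.25),
        ("dialysis", 0.01, 8000.0, 0.5),
    )
    enrollment_gap_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.epilepsy_prevalence, self.refractory_fraction,
            self.switch_prob_refractory, self.switch_prob_nonrefractory,
            self.case_first_year_risk, self.case_three_year_risk,
            self.epilepsy_admission_fraction, self.status_epilepticus_fraction,
            self.enrollment_gap_prob, self.gp_diagnosis_prob,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.refractory_fraction > 0 and len(self.aed_substance_pool) < 4:
            raise ValueError("substance pool must hold >=4 substances for a refractory subgroup")
        if self.switch_prob_refractory <= self.switch_prob_nonrefractory:
            raise ValueError("refractory switch probability must exceed non-refractory")
        if self.background_annual_hazard < 0:
            raise ValueError("hazards must be non-negative")
        if self.case_first_year_risk > self.case_three_year_risk:
            raise ValueError("first-year risk cannot exceed three-year risk")

    @property
    def annual_admission_prob_cases(self) -> float:
        """P(>=1 admission in a year) implied by the gamma-Poisson mixture."""
        k, mu = self.admission_shape_cases, self.admission_mu_cases
        return 1.0 - (k / (k + mu)) ** k

    @property
    def annual_admission_prob_controls(self) -> float:
        k, mu = self.admission_shape_controls, self.admission_mu_controls
        return 1.0 - (k / (k + mu)) ** k


@dataclass
class GroundTruth:
    """Oracle labels: who is epileptic / realized-refractory, the realized
    index date, and per-follow-up-year realized admission counts."""

    frame: pd.DataFrame  # one row per insurant

    @property
    def refractory_ids(self) -> set[str]:
        f = self.frame
        return set(f.loc[f["is_refractory"], "insurant_id"])


def default_params(scale: str = "small", seed: int = 0) -> SimulationParams:
    """Preset parameter bundles.

    ``small`` (20,000 insurants, refractory fraction 10% of epileptics) runs
    in well under a minute and yields a workable handful of cases.
    ``reference`` scales the refractory fraction so that the expected case
    yield matches 769 cases per 4 million insured (~1.9 per 10,000) at
    n = 200,000.
    """
    if scale == "small":
        return SimulationParams(n_insurants=20_000, refractory_fraction=0.10, seed=seed)
    if scale == "reference":
        return SimulationParams(n_insurants=200_000, refractory_fraction=0.024, seed=seed)
    raise ValueError(f"unknown scale {scale!r}")


def _lognormal_mu(mean: float, sigma: float) -> float:
    return np.log(mean) - sigma**2 / 2.0


def _uniform_date(rng, start: date, end: date) -> date:
    """Uniform date in [start, end] inclusive."""
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _true_index_scan(
    dispensations: list[tuple[date, str]],
    window_days: int,
    id_start: date,
    id_end: date,
    k: int = 4,
) -> date | None:
    """Brute-force rolling-window scan: earliest dispense date d in the
    identification interval with >= k distinct substances dispensed in
    (d - window_days, d]. Independent of the phenotyping module."""
    if not dispensations:
        return None
    pairs = sorted(set(dispensations))
    window = timedelta(days=window_days)
    for d in sorted({dd for dd, _ in pairs if id_start <= dd <= id_end}):
        distinct = {c for dd, c in pairs if d - window < dd <= d}
        if len(distinct) >= k:
            return d
    return None


def simulate_claims(params: SimulationParams) -> tuple[ClaimsDatabase, GroundTruth]:
    """Generate a claims database and its ground truth labels."""
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    streams = ss.spawn(8)
    rng_pop, rng_drugs, rng_death, rng_adm, rng_com, rng_contact, rng_anc, rng_rx = (
        np.random.default_rng(s) for s in streams
    )

    n = params.n_insurants
    obs_start, obs_end = params.observation_start, params.observation_end
    years = list(range(obs_start.year, obs_end.year + 1))

    # --- population -------------------------------------------------------
    ids = np.array([f"P{i:07d}" for i in range(n)])
    bands = params.pyramid
    weights = np.array([b[3] for b in bands], dtype=float)
    weights /= weights.sum()
    band_idx = rng_pop.choice(len(bands), size=n, p=weights)
    age_lo = np.array([bands[i][0] for i in band_idx])
    age_hi = np.array([bands[i][1] for i in band_idx])
    sex = np.array([bands[i][2] for i in band_idx])
    age = rng_pop.integers(age_lo, age_hi + 1)
    birth_year = obs_start.year - age

    enroll_start = np.full(n, obs_start, dtype=object)
    enroll_end = np.full(n, obs_end, dtype=object)
    gap = rng_pop.random(n) < params.enrollment_gap_prob
    for i in np.flatnonzero(gap):
        if rng_pop.random() < 0.5:
            enroll_start[i] = _uniform_date(rng_pop, obs_start, date(2009, 12, 31))
        else:
            enroll_end[i] = _uniform_date(rng_pop, date(2012, 1, 1), obs_end)

    has_epilepsy = rng_pop.random(n) < params.epilepsy_prevalence
    assigned_refractory = has_epilepsy & (rng_pop.random(n) < params.refractory_fraction)

    # --- drug accrual schedule (epileptics) -------------------------------
    # substances: list per insurant of (accrual_date, atc, active_until)
    accrual: dict[int, list[tuple[date, str, date]]] = {}
    scheduled_index: dict[int, date] = {}
    pool = list(params.aed_substance_pool)
    q_mean = params.substance_active_quarters_mean

    def _active_until(rng, start: date) -> date:
        quarters = int(rng.geometric(1.0 / q_mean))
        return start + timedelta(days=91 * quarters)

    for i in np.flatnonzero(has_epilepsy):
        rng = rng_drugs
        subs: list[tuple[date, str, date]] = []
        order = [pool[j] for j in rng.permutation(len(pool))]
        if assigned_refractory[i]:
            idx_target = _uniform_date(
                rng,
                params.identification_start + timedelta(days=14),
                params.identification_end - timedelta(days=14),
            )
            max_lat = min(params.window_days - 14, (idx_target - obs_start).days - 21)
            lat = float(np.clip(rng.normal(params.latency_mean_days, params.latency_sd_days), 45, max_lat))
            first = idx_target - timedelta(days=int(round(lat)))
            gaps = rng.dirichlet([1.0, 1.0, 1.0]) * lat
            dates = [first]
            acc = 0.0
            for g in gaps:
                acc += g
                dates.append(first + timedelta(days=int(round(acc))))
            dates[3] = idx_target  # the fourth lands exactly on the target
            for d, code in zip(dates, order[:4]):
                subs.append((d, code, _active_until(rng, d)))
            scheduled_index[i] = idx_target
            # follow-up additions
            used = 4
            q = idx_target
            fu_end = min(idx_target + timedelta(days=3 * 365), obs_end)
            while q < fu_end and used < len(order):
                q = q + timedelta(days=91)
                if q >= fu_end:
                    break
                if rng.random() < params.switch_prob_refractory:
                    d = q + timedelta(days=int(rng.integers(0, 45)))
                    if d <= obs_end:
                        subs.append((d, order[used], _active_until(rng, d)))
                        used += 1
        else:
            cap = params.nonrefractory_substance_cap
            first = _uniform_date(rng, obs_start, obs_end - timedelta(days=180))
            subs.append((first, order[0], obs_end))  # stable long-term therapy
            used = 1
            q = first
            while q < obs_end and used < len(order):
                q = q + timedelta(days=91)
                if cap is not None and used >= cap:
                    break
                if rng.random() < params.switch_prob_nonrefractory:
                    d = q + timedelta(days=int(rng.integers(0, 45)))
                    if d <= obs_end:
                        subs.append((d, order[used], _active_until(rng, d)))
                        used += 1
        accrual[i] = subs

    # --- mortality --------------------------------------------------------
    death = np.full(n, None, dtype=object)
    daily_bg = params.background_annual_hazard / 365.0
    for i in range(n):
        start_i, end_i = enroll_start[i], enroll_end[i]
        if assigned_refractory[i] and i in scheduled_index:
            idx = scheduled_index[i]
            # background risk before index
            if daily_bg > 0:
                t = rng_death.exponential(1.0 / daily_bg)
                pre_days = (idx - start_i).days
                if t < pre_days:
                    death[i] = start_i + timedelta(days=int(t))
                    continue
            u = rng_death.random()
            if u < params.case_first_year_risk:
                death[i] = idx + timedelta(days=int(rng_death.integers(0, 365)))
            elif u < params.case_three_year_risk:
                death[i] = idx + timedelta(days=int(rng_death.integers(365, 3 * 365)))
            else:
                if daily_bg > 0:
                    t = rng_death.exponential(1.0 / daily_bg)
                    post = idx + timedelta(days=3 * 365)
                    cand = post + timedelta(days=int(t))
                    if cand <= end_i:
                        death[i] = cand
        else:
            if daily_bg > 0:
                t = rng_death.exponential(1.0 / daily_bg)
                cand = start_i + timedelta(days=int(t))
                if cand <= end_i:
                    death[i] = cand
    # deaths outside the enrollment interval are unobserved in claims
    for i in range(n):
        if death[i] is not None and not (enroll_start[i] <= death[i] <= enroll_end[i]):
            death[i] = None
    # death truncates the observable event window
    stop_date = np.array(
        [min(enroll_end[i], death[i]) if death[i] is not None else enroll_end[i] for i in range(n)],
        dtype=object,
    )

    # --- dispensations ----------------------------------------------------
    rx_rows: list[tuple[str, date, str, str, float]] = []
    aed_mu = _lognormal_mu(params.aed_cost_mean, params.aed_cost_sigma)
    substance_names = {code: code for code in pool}
    realized: dict[int, list[tuple[date, str]]] = {}
    for i, subs in accrual.items():
        events: list[tuple[date, str]] = []
        for (start_d, code, until) in subs:
            stop = min(until, stop_date[i], obs_end)
            d = start_d
            while d <= stop:
                if d >= enroll_start[i] and d >= obs_start:
                    events.append((d, code))
                jitter = int(rng_rx.integers(-10, 11))
                d = d + timedelta(days=90 + jitter)
        events.sort()
        realized[i] = events
        for (d, code) in events:
            cost = float(np.round(rng_rx.lognormal(aed_mu, params.aed_cost_sigma), 2))
            rx_rows.append((ids[i], d, code, substance_names[code], cost))

    # background (non-anticonvulsant) dispensations for everyone
    bg_codes = ("M01AE01", "A02BC02", "J01DC02", "N02BB02", "C07AB02")
    bg_mu = _lognormal_mu(params.background_rx_cost_mean, 0.5)
    n_bg = rng_rx.poisson(params.background_rx_rate * 6, size=n)
    for i in range(n):
        for _ in range(int(n_bg[i])):
            d = _uniform_date(rng_rx, enroll_start[i], obs_end)
            if d > stop_date[i]:
                continue
            code = bg_codes[int(rng_rx.integers(0, len(bg_codes)))]
            cost = float(np.round(rng_rx.lognormal(bg_mu, 0.5), 2))
            rx_rows.append((ids[i], d, code, code, cost))

    # --- diagnoses --------------------------------------------------------
    dx_rows: list[tuple[str, str, str, str, str]] = []
    epilepsy_codes = ("G40.1", "G40.2", "G40.3", "G40.9")
    for i in np.flatnonzero(has_epilepsy):
        onset = min(accrual[i][0][0], stop_date[i]) if accrual[i] else enroll_start[i]
        onset = max(onset, enroll_start[i])
        emitted = False
        d = onset
        while d <= stop_date[i]:
            if rng_com.random() < params.gp_diagnosis_prob:
                code = epilepsy_codes[int(rng_com.integers(0, len(epilepsy_codes)))]
                dx_rows.append((ids[i], quarter_of_date(d), code, "outpatient", "secondary"))
                emitted = True
            d = d + timedelta(days=91)
        if not emitted:
            q_date = min(max(onset, enroll_start[i]), stop_date[i])
            code = epilepsy_codes[int(rng_com.integers(0, len(epilepsy_codes)))]
            dx_rows.append((ids[i], quarter_of_date(q_date), code, "outpatient", "secondary"))

    # comorbidity diagnoses: annual Bernoulli per block
    com = params.comorbidity
    p_case = np.array([c[1] for c in com])
    p_ctrl = np.array([c[2] for c in com])
    for i in range(n):
        probs = p_case if assigned_refractory[i] else p_ctrl
        for y in years:
            y_start, y_end = date(y, 1, 1), date(y, 12, 31)
            if y_start > stop_date[i] or y_end < enroll_start[i]:
                continue
            draws = rng_com.random(len(com)) < probs
            for j in np.flatnonzero(draws):
                d = _uniform_date(rng_com, max(y_start, enroll_start[i]), min(y_end, stop_date[i]))
                dx_rows.append((ids[i], quarter_of_date(d), com[j][0], "outpatient", "secondary"))

    # --- admissions -------------------------------------------------------
    adm_rows: list[tuple] = []
    frailty_case = rng_adm.gamma(params.admission_shape_cases, 1.0 / params.admission_shape_cases, size=n)
    frailty_ctrl = rng_adm.gamma(params.admission_shape_controls, 1.0 / params.admission_shape_controls, size=n)
    drg_mu_case = _lognormal_mu(params.drg_cost_mean_cases, params.drg_cost_sigma)
    drg_mu_ctrl = _lognormal_mu(params.drg_cost_mean_controls, params.drg_cost_sigma)
    los_mu_case = _lognormal_mu(params.los_mean_cases, params.los_sigma)
    los_mu_ctrl = _lognormal_mu(params.los_mean_controls, params.los_sigma)

    for i in range(n):
        is_case = bool(assigned_refractory[i]) and i in scheduled_index
        mu = params.admission_mu_cases if is_case else params.admission_mu_controls
        g = frailty_case[i] if is_case else frailty_ctrl[i]
        for y in years:
            y_start, y_end = date(y, 1, 1), date(y, 12, 31)
            lo = max(y_start, enroll_start[i])
            hi = min(y_end, stop_date[i])
            if lo > hi:
                continue
            k_adm = rng_adm.poisson(g * mu * ((hi - lo).days + 1) / 365.0)
            for _ in range(int(k_adm)):
                admit = _uniform_date(rng_adm, lo, hi)
                if is_case and rng_adm.random() < params.epilepsy_admission_fraction:
                    if rng_adm.random() < params.status_epilepticus_fraction:
                        primary = "G41.0"
                    else:
                        primary = epilepsy_codes[int(rng_adm.integers(0, len(epilepsy_codes)))]
                    los_mean_mu = los_mu_case
                    ops = []
                    if rng_adm.random() < params.ops_complex_prob:
                        ops.append(f"8-972.{int(rng_adm.integers(0, 3))}")
                    if rng_adm.random() < params.ops_video_eeg_prob:
                        ops.append("1-210")
                    if rng_adm.random() < params.ops_surgery_prob:
                        ops.append("5-010")
                    cost = float(np.round(rng_adm.lognormal(drg_mu_case, params.drg_cost_sigma), 2))
                else:
                    if has_epilepsy[i]:
                        primary = _BACKGROUND_PRIMARY[int(rng_adm.integers(0, len(_BACKGROUND_PRIMARY)))]
                    else:
                        primary = _BACKGROUND_PRIMARY[int(rng_adm.integers(0, len(_BACKGROUND_PRIMARY)))]
                    los_mean_mu = los_mu_case if is_case else los_mu_ctrl
                    ops = []
                    cost = float(
                        np.round(
                            rng_adm.lognormal(drg_mu_case if is_case else drg_mu_ctrl, params.drg_cost_sigma), 2
                        )
                    )
                los = max(1, int(round(rng_adm.lognormal(los_mean_mu, params.los_sigma))))
                discharge = min(admit + timedelta(days=los - 1), obs_end)
                n_sec = int(rng_adm.integers(0, 3))
                sec = [
                    _SECONDARY_POOL[int(rng_adm.integers(0, len(_SECONDARY_POOL)))]
                    for _ in range(n_sec)
                ]
                adm_rows.append(
                    (ids[i], admit, discharge, primary, ";".join(sec), ";".join(ops), cost)
                )
                # mirror inpatient diagnoses into the diagnoses table
                dx_rows.append((ids[i], quarter_of_date(admit), primary, "inpatient", "primary"))
                for s in sec:
                    dx_rows.append((ids[i], quarter_of_date(admit), s, "inpatient", "secondary"))

    # --- outpatient contacts ---------------------------------------------
    oc_rows: list[tuple] = []
    for i in range(n):
        is_case = bool(assigned_refractory[i]) and i in scheduled_index
        spec_params = params.contacts_case if is_case else params.contacts_control
        for y in years:
            y_start, y_end = date(y, 1, 1), date(y, 12, 31)
            lo = max(y_start, enroll_start[i])
            hi = min(y_end, stop_date[i])
            if lo > hi:
                continue
            frac = ((hi - lo).days + 1) / 365.0
            for spec, (p_any, mean_contacts) in spec_params.items():
                if spec == "neuropediatrician" and (y - birth_year[i]) >= 18:
                    continue
                if rng_contact.random() >= p_any * frac:
                    continue
                total = 1 + rng_contact.poisson(max(mean_contacts - 1.0, 0.0))
                qcounts = rng_contact.multinomial(total, [0.25] * 4)
                prescriber = (
                    is_case
                    and spec in params.prescriber_share
                    and rng_contact.random() < params.prescriber_share[spec]
                )
                for qn in range(4):
                    if qcounts[qn] == 0:
                        continue
                    q_label = f"{y}Q{qn + 1}"
                    cost = float(np.round(qcounts[qn] * params.contact_cost_eur, 2))
                    oc_rows.append((ids[i], q_label, spec, int(qcounts[qn]), bool(prescriber), cost))

    # --- ancillary cost items --------------------------------------------
    anc_rows: list[tuple] = []
    for i in range(n):
        is_case = bool(assigned_refractory[i]) and i in scheduled_index
        for (cat, p_any, mean_eur, ctrl_mult) in params.ancillary_spec:
            p = p_any if is_case else p_any * ctrl_mult
            for y in years:
                y_start, y_end = date(y, 1, 1), date(y, 12, 31)
                lo = max(y_start, enroll_start[i])
                hi = min(y_end, stop_date[i])
                if lo > hi:
                    continue
                if rng_anc.random() < p * (((hi - lo).days + 1) / 365.0):
                    d = _uniform_date(rng_anc, lo, hi)
                    cost = float(np.round(rng_anc.lognormal(_lognormal_mu(mean_eur, 0.6), 0.6), 2))
                    anc_rows.append((ids[i], d, cat, cost))

    # --- assemble tables --------------------------------------------------
    insurants = pd.DataFrame(
        {
            "insurant_id": ids,
            "birth_year": birth_year,
            "sex": sex,
            "enroll_start": pd.to_datetime(enroll_start),
            "enroll_end": pd.to_datetime(enroll_end),
            "death_date": pd.to_datetime(death),
        }
    )
    diagnoses = pd.DataFrame(
        dx_rows, columns=["insurant_id", "quarter", "icd_code", "setting", "position"]
    ).sort_values(["insurant_id", "quarter", "icd_code"], kind="stable").reset_index(drop=True)
    dispensations = pd.DataFrame(
        rx_rows, columns=["insurant_id", "dispense_date", "atc_code", "substance_name", "cost"]
    )
    dispensations["dispense_date"] = pd.to_datetime(dispensations["dispense_date"])
    dispensations = dispensations.sort_values(
        ["insurant_id", "dispense_date", "atc_code"], kind="stable"
    ).reset_index(drop=True)
    admissions = pd.DataFrame(
        adm_rows,
        columns=["insurant_id", "admit_date", "discharge_date", "primary_icd", "secondary_icds", "ops_codes", "drg_cost"],
    )
    for c in ("admit_date", "discharge_date"):
        admissions[c] = pd.to_datetime(admissions[c])
    admissions = admissions.sort_values(["insurant_id", "admit_date"], kind="stable").reset_index(drop=True)
    outpatient = pd.DataFrame(
        oc_rows, columns=["insurant_id", "quarter", "specialty", "n_contacts", "prescriber_of_aed", "cost"]
    ).sort_values(["insurant_id", "quarter", "specialty"], kind="stable").reset_index(drop=True)
    ancillary = pd.DataFrame(anc_rows, columns=["insurant_id", "service_date", "category", "cost"])
    if len(ancillary):
        ancillary["service_date"] = pd.to_datetime(ancillary["service_date"])
        ancillary = ancillary.sort_values(["insurant_id", "service_date", "category"], kind="stable").reset_index(drop=True)

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

    # --- ground truth -----------------------------------------------------
    true_index = np.full(n, None, dtype=object)
    is_refractory = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(has_epilepsy):
        idx = _true_index_scan(
            realized.get(i, []),
            params.window_days,
            params.identification_start,
            params.identification_end,
        )
        if idx is None:
            continue
        if not (enroll_start[i] <= idx <= enroll_end[i]):
            continue
        true_index[i] = idx
        is_refractory[i] = True

    fu_counts = {f"n_admissions_fu{y}": np.full(n, np.nan) for y in (1, 2, 3)}
    adm_by_id = admissions.groupby("insurant_id")["admit_date"].apply(list) if len(admissions) else {}
    for i in np.flatnonzero(is_refractory):
        idx = true_index[i]
        dates = adm_by_id.get(ids[i], []) if len(admissions) else []
        for y in (1, 2, 3):
            lo = pd.Timestamp(idx) + pd.Timedelta(days=365 * (y - 1))
            hi = pd.Timestamp(idx) + pd.Timedelta(days=365 * y)
            fu_counts[f"n_admissions_fu{y}"][i] = sum(1 for d in dates if lo <= d < hi)

    truth = GroundTruth(
        pd.DataFrame(
            {
                "insurant_id": ids,
                "has_epilepsy": has_epilepsy,
                "assigned_refractory": assigned_refractory,
                "is_refractory": is_refractory,
                "true_index_date": [d.isoformat() if d is not None else "" for d in true_index],
                "death_date": [d.isoformat() if d is not None else "" for d in death],
                **fu_counts,
            }
        )
    )
    return db, truth
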