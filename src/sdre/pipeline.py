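"""End-to-end analysis pipeline: (simulate | load) -> phenotype -> match ->
burden -> survival, with a reproducibility manifest.

The report directory a run produces contains:

* ``cases.csv`` — phenotyped SDRE cases with index dates,
* ``matched.csv`` — case->control pairs and pseudo-index dates,
* ``burden_table.csv`` — per-period resource-use metrics for both cohorts,
* ``costs.csv`` — per-period direct-cost components for both cohorts,
* ``prescriptions.csv`` — per-substance period shares,
* ``comorbidity.csv`` — case vs control prevalence with chi-square tests,
* ``survival_sdre.csv`` / ``survival_control.csv`` — product-limit curves,
* ``manifest.json`` — config, seeds, version and row counts.

Identical config + seeds reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import (
    ALL_PERIODS,
    contact_summary,
    cost_summary,
    costs_to_frame,
    default_code_sets,
    hospitalization_summary,
    load_code_sets,
    prescription_pattern,
    prevalence_compare,
    procedure_uptake,
    status_epilepticus_hospitalized,
)
from .claims_model import ClaimsDatabase, load_claims, validate, write_claims
from .matching import MatchedCohort, match_controls, matched_to_frame
from .phenotyping import PhenotypeConfig, SdreCase, cases_to_frame, identify_sdre_cases
from .stats import cumulative_mortality, km_curve
from .synthetic_claims import SimulationParams, default_params, simulate_claims

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_summary", "survival_inputs"]

log = logging.getLogger("sdre")

OPS_PREFIXES = ("8-972", "1-210", "1-211", "5-010")


class PipelineError(Exception):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # 'simulate' | 'load'
    claims_dir: str | None = None  # load mode input / simulate mode optional dump
    scale: str = "small"
    sim_params: SimulationParams | None = None
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    ratio: int = 20
    seed: int = 7
    match_seed: int = 11
    code_sets_path: str | None = None
    cost_mode: str = "index_anchored"
    out_dir: str = "report"
    write_claims_copy: bool = False

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load":
            if not self.claims_dir or not Path(self.claims_dir).exists():
                raise ValueError(f"claims_dir {self.claims_dir!r} does not exist")
        if self.cost_mode not in ("index_anchored", "calendar"):
            raise ValueError(f"unknown cost_mode {self.cost_mode!r}")


def survival_inputs(
    db: ClaimsDatabase, anchors: dict[str, date]
) -> tuple[np.ndarray, np.ndarray]:
    """Durations (days from anchor, >=1) and event flags for a cohort.

    Follow-up runs from the (pseudo-)index to death or to censoring at the
    end of enrollment/observation; a death on the index day is counted at
    day 1 (the product-limit estimator needs positive durations).
    """
    ins = db.insurants.set_index("insurant_id")
    durations, events = [], []
    obs_end = pd.Timestamp(db.observation_end)
    for pid, anchor in anchors.items():
        row = ins.loc[pid]
        a = pd.Timestamp(anchor)
        end = min(pd.Timestamp(row["enroll_end"]), obs_end)
        dd = row["death_date"]
        if pd.notna(dd) and dd >= a:
            durations.append(max(1, (dd - a).days))
            events.append(True)
        else:
            durations.append(max(1, (end - a).days))
            events.append(False)
    return np.asarray(durations, dtype=float), np.asarray(events, dtype=bool)


def run_pipeline(config: PipelineConfig, db: ClaimsDatabase | None = None):
    """Run all stages and write the report directory; returns its Path.

    A pre-built database may be passed to skip the input stage (used by the
    tests and the acceptance script to avoid a disk round-trip).
    """
    try:
        config.validate()
    except ValueError as e:
        raise PipelineError("config", str(e)) from e
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- input stage
    truth = None
    if db is None:
        if config.mode == "simulate":
            params = config.sim_params or default_params(config.scale, seed=config.seed)
            db, truth = simulate_claims(params)
        else:
            try:
                db = load_claims(config.claims_dir)
            except Exception as e:
                raise PipelineError("load", str(e)) from e
    violations = validate(db)
    if violations:
        raise PipelineError("validate", f"{len(violations)} violations, first: {violations[0]}")
    log.info("input: %s", db.row_counts())
    if config.write_claims_copy and config.mode == "simulate" and config.claims_dir:
        write_claims(db, config.claims_dir)

    # --- phenotype
    cases = identify_sdre_cases(db, config.phenotype)
    log.info("phenotype: %d cases", len(cases))
    cases_to_frame(cases).to_csv(out / "cases.csv", index=False)

    # --- match
    cohort = match_controls(
        db, cases, ratio=config.ratio, seed=config.match_seed,
        epilepsy_icd_prefix=config.phenotype.epilepsy_icd_prefix,
    )
    log.info("match: %d controls (%d shortfalls)", len(cohort.pairs), len(cohort.shortfalls))
    matched_to_frame(cohort).to_csv(out / "matched.csv", index=False)

    case_anchors = {c.insurant_id: c.index_date for c in cases}
    control_anchors = dict(cohort.pseudo_index)

    # --- burden
    burden_frames = []
    for label, anchors in (("sdre", case_anchors), ("control", control_anchors)):
        if not anchors:
            continue
        burden_frames.append(hospitalization_summary(db, anchors, cohort=label))
        burden_frames.append(
            hospitalization_summary(db, anchors, epilepsy_specific=True, cohort=label)
        )
        burden_frames.append(contact_summary(db, anchors, cohort=label))
    if case_anchors:
        burden_frames.append(procedure_uptake(db, case_anchors, OPS_PREFIXES, cohort="sdre"))
        k, n_risk, prop = status_epilepticus_hospitalized(db, case_anchors)
        burden_frames.append(
            pd.DataFrame(
                [
                    {
                        "cohort": "sdre", "period": "fu_total",
                        "metric": "status_epilepticus_hospitalized_share",
                        "numerator": k, "denominator": n_risk, "value": prop,
                        "dispersion": np.nan,
                    }
                ]
            )
        )
    burden = (
        pd.concat(burden_frames, ignore_index=True)
        if burden_frames
        else pd.DataFrame(columns=["cohort", "period", "metric", "numerator", "denominator", "value", "dispersion"])
    )
    burden.to_csv(out / "burden_table.csv", index=False)

    # --- prescriptions
    if case_anchors:
        shares, rx_stats = prescription_pattern(db, case_anchors)
        shares.to_csv(out / "prescriptions.csv", index=False)
    else:
        rx_stats = {"distinct_aeds_fu_mean": float("nan"), "distinct_aeds_fu_sd": float("nan"), "n": 0}
        pd.DataFrame(columns=["cohort", "period", "metric", "numerator", "denominator", "value", "dispersion"]).to_csv(
            out / "prescriptions.csv", index=False
        )

    # --- comorbidity prevalence
    code_sets = (
        load_code_sets(config.code_sets_path) if config.code_sets_path else default_code_sets()
    )
    com_rows = []
    if case_anchors and control_anchors:
        for cs in code_sets.values():
            com_rows.append(prevalence_compare(db, case_anchors, control_anchors, cs, period="fu1"))
    pd.DataFrame(com_rows).to_csv(out / "comorbidity.csv", index=False)

    # --- costs
    cost_frames = []
    for label, anchors in (("sdre", case_anchors), ("control", control_anchors)):
        if not anchors:
            continue
        summaries = cost_summary(db, anchors, mode=config.cost_mode, cohort=label)
        cost_frames.append(costs_to_frame(summaries, cohort=label))
    (
        pd.concat(cost_frames, ignore_index=True)
        if cost_frames
        else pd.DataFrame()
    ).to_csv(out / "costs.csv", index=False)

    # --- survival
    mortality = {}
    for label, anchors in (("sdre", case_anchors), ("control", control_anchors)):
        if anchors:
            dur, ev = survival_inputs(db, anchors)
            curve = km_curve(dur, ev)
            curve.to_frame().to_csv(out / f"survival_{label}.csv", index=False)
            mortality[label] = cumulative_mortality(curve, 3 * 365)
        else:
            pd.DataFrame(columns=["time", "n_at_risk", "n_events", "n_censored", "survival", "variance"]).to_csv(
                out / f"survival_{label}.csv", index=False
            )
            mortality[label] = float("nan")

    manifest = {
        "version": __version__,
        "mode": config.mode,
        "scale": config.scale if config.mode == "simulate" else None,
        "seed": config.seed,
        "match_seed": config.match_seed,
        "ratio": config.ratio,
        "cost_mode": config.cost_mode,
        "phenotype": {
            "epilepsy_icd_prefix": config.phenotype.epilepsy_icd_prefix,
            "aed_atc_prefix": config.phenotype.aed_atc_prefix,
            "k_distinct": config.phenotype.k_distinct,
            "window_days": config.phenotype.window_days,
            "identification_start": config.phenotype.identification_start.isoformat(),
            "identification_end": config.phenotype.identification_end.isoformat(),
        },
        "row_counts": db.row_counts(),
        "n_cases": len(cases),
        "n_controls": len(set(cohort.control_ids)),
        "n_shortfalls": len(cohort.shortfalls),
        "three_year_mortality": mortality,
        "distinct_aeds_fu": rx_stats,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


REQUIRED_TABLES = (
    "cases.csv", "matched.csv", "burden_table.csv", "costs.csv",
    "prescriptions.csv", "survival_sdre.csv", "survival_control.csv", "manifest.json",
)


def render_summary(report_dir) -> str:
    """Headline numbers of a finished run, in report order: cohort size,
    demographics, hospitalization, mortality, costs."""
    report_dir = Path(report_dir)
    for name in REQUIRED_TABLES:
        if not (report_dir / name).exists():
            raise FileNotFoundError(f"missing report table {name} in {report_dir}")
    manifest = json.loads((report_dir / "manifest.json").read_text())
    cases = pd.read_csv(report_dir / "cases.csv")
    lines = [f"{len(cases)} cases identified"]
    if len(cases) == 0:
        return "\n".join(lines)
    lines.append(f"{manifest['n_controls']} matched controls (ratio {manifest['ratio']}:1)")
    burden = pd.read_csv(report_dir / "burden_table.csv")

    def metric(cohort, period, name):
        m = burden[(burden.cohort == cohort) & (burden.period == period) & (burden.metric == name)]
        return float(m["value"].iloc[0]) if len(m) else float("nan")

    for y in ("fu1", "fu2", "fu3"):
        sdre = metric("sdre", y, "hospitalized_share")
        ctrl = metric("control", y, "hospitalized_share")
        lines.append(f"hospitalization {y}: sdre {sdre:.1%} vs control {ctrl:.1%}")
    mort = manifest["three_year_mortality"]
    lines.append(
        f"3-year mortality: sdre {mort.get('sdre', float('nan')):.1%} "
        f"vs control {mort.get('control', float('nan')):.1%}"
    )
    costs = pd.read_csv(report_dir / "costs.csv")
    sdre_costs = costs[(costs.cohort == "sdre") & (costs.period.isin(["fu1", "fu2", "fu3"]))]
    if len(sdre_costs):
        lines.append(
            "annual direct costs per SDRE patient: "
            + ", ".join(f"{p}: EUR {v:,.0f}" for p, v in zip(sdre_costs.period, sdre_costs.mean_total_per_person))
        )
    return "\n".join(lines)
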