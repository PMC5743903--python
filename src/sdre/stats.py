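"""Statistical kernel: Pearson chi-square for 2x2 tables and the
Kaplan-Meier product-limit estimator.

Both are implemented directly from their defining formulas so that every
number in the report tables is traceable; the test suite cross-checks them
against scipy and lifelines. P-values are two-sided; no multiple-testing
adjustment is applied anywhere in the pipeline (the analyses are explorative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "TwoByTwo",
    "SurvivalCurve",
    "chi_square_2x2",
    "km_curve",
    "cumulative_mortality",
    "logrank_test",
    "format_p",
]


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table.

    Layout: rows are cohorts (exposed / unexposed), columns are outcome
    (event / no event)::

        a  b      exposed with event    | exposed without
        c  d      unexposed with event  | unexposed without
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("grand total must be positive")

    @classmethod
    def from_proportions(cls, k1: int, n1: int, k2: int, n2: int) -> "TwoByTwo":
        """Build from events/size per cohort: k1/n1 vs k2/n2."""
        return cls(k1, n1 - k1, k2, n2 - k2)


def chi_square_2x2(t: TwoByTwo, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test for a 2x2 table.

    Returns ``(statistic, df, p_value)`` with df = 1. The statistic is
    sum((O-E)^2 / E) over the four cells with expectations from the margins;
    ``correction`` applies Yates' continuity correction. A zero margin makes
    an expected cell zero and is rejected.
    """
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        which = "row" if (row == 0).any() else "column"
        raise ValueError(f"zero {which} margin: chi-square undefined")
    expected = np.outer(row, col) / n
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(_chi2_dist.sf(stat, df=1))
    return stat, 1, p


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate.

    One row per distinct event time: number at risk, events, censorings at
    that time, the survival estimate S(t) just after it, and the Greenwood
    variance of S(t).
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    variance: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S=1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "n_censored": self.n_censored,
                "survival": self.survival,
                "variance": self.variance,
            }
        )


def km_curve(durations, event_flags) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``durations`` are days from time zero to event or censoring;
    ``event_flags`` is truthy for an observed event (death), falsy for
    censoring. Subjects censored at an event time are considered still at
    risk for that event time (censoring is handled after events at ties).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.size == 0:
        z = np.array([])
        return SurvivalCurve(z, z, z, z, z, z)
    if (t <= 0).any():
        raise ValueError("durations must be positive")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times = np.unique(t[e]) if e.any() else np.array([], dtype=float)

    at_risk = np.empty(times.size)
    deaths = np.empty(times.size)
    cens = np.empty(times.size)
    surv = np.empty(times.size)
    var = np.empty(times.size)

    s = 1.0
    greenwood = 0.0
    for i, ti in enumerate(times):
        n_i = int((t >= ti).sum())  # censored-at-ti still at risk
        d_i = int(((t == ti) & e).sum())
        c_i = int(((t == ti) & ~e).sum())
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            greenwood += d_i / (n_i * (n_i - d_i))
        at_risk[i], deaths[i], cens[i] = n_i, d_i, c_i
        surv[i] = s
        var[i] = s * s * greenwood
    return SurvivalCurve(times, at_risk, deaths, cens, surv, var)


def cumulative_mortality(curve: SurvivalCurve, horizon_days: float) -> float:
    """1 - S(horizon): cumulative death probability by the horizon."""
    if horizon_days < 0:
        raise ValueError("horizon must be non-negative")
    return 1.0 - curve.survival_at(horizon_days)


def logrank_test(durations_a, events_a, durations_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank test (beyond the core report; provided for curve
    comparisons). Returns (chi-square statistic, p-value)."""
    from lifelines.statistics import logrank_test as _lr

    res = _lr(durations_a, durations_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def format_p(p: float) -> str:
    """Report-table p-value style: '<0.001' below that threshold, else three
    significant digits."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3g}"
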