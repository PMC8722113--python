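"""Payoff accrual and strategy comparison.

Life-years, QALYs and costs are accrued per cycle and discounted to
diagnosis at an annual rate (default 1.5%) with annual compounding,
``(1+r)^-t``, applied at cycle start. Utilities of coexisting conditions
combine multiplicatively. Costs are split into PLGG treatment (surgery,
chemotherapy, radiation, the molecular test), adverse-event costs (acute
onset plus per-year management), and background healthcare expenditure
unrelated to PLGG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import AE_CLASSES
from .engine import ArmResult, DEATH_EVENT_NAMES, Trajectory
from .tables import CostTable, DISEASE_STAGES, UtilityTable


def discount_factor(t: float, r: float) -> float:
    """Present-value weight ``(1+r)^-t`` for a payoff ``t`` years out."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r}")
    return (1.0 + r) ** (-t)


def combined_utility(base: float, active_ae_multipliers: Iterable[float]) -> float:
    """Multiplicative utility of a disease stage with coexisting AEs."""
    if not 0.0 <= base <= 1.0:
        raise ValueError(f"base utility must be in [0, 1], got {base}")
    u = base
    for m in active_ae_multipliers:
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"AE utility multiplier must be in [0, 1], got {m}")
        u *= m
    return u


@dataclass(frozen=True)
class OutcomeSummary:
    """Discounted life-years, QALYs and costs (means over patients, or a
    single patient), with optional percentile intervals per field."""

    life_years: float
    qalys: float
    cost_plgg: float
    cost_ae: float
    cost_background: float
    cost_total: float
    life_years_undiscounted: float | None = None
    intervals: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValueError("QALYs cannot exceed (discounted) life-years")
        parts = self.cost_plgg + self.cost_ae + self.cost_background
        if abs(parts - self.cost_total) > 1e-6:
            raise ValueError("cost components must sum to cost_total")
        for name in ("life_years", "qalys", "cost_plgg", "cost_ae", "cost_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def accrue(
    trajectory: Trajectory,
    costs: CostTable,
    utilities: UtilityTable,
    r: float = 0.015,
) -> OutcomeSummary:
    """Discounted payoffs of one complete trajectory.

    Per-cycle payoffs use the state occupied at cycle start; the death cycle
    credits half a cycle. One-time costs (surgery and test at diagnosis,
    RT/chemo courses, acute AE onset) are discounted at the start of the
    cycle in which they occur.
    """
    if set(AE_CLASSES) - set(utilities.ae_utility_multiplier):
        raise ValueError("utility table does not cover the trajectory's AE classes")
    dt = trajectory.cycle_length
    stage_util = [utilities.baseline_utility[s] for s in DISEASE_STAGES]
    ae_mult = [utilities.ae_utility_multiplier[c] for c in AE_CLASSES]
    ae_ann = [costs.ae_annual_cost[c] for c in AE_CLASSES]
    ae_acute = {f"ae_onset_{c}": costs.ae_acute_cost[c] for c in AE_CLASSES}

    ly = ly_d = qaly = c_ae = c_bg = 0.0
    c_plgg = costs.surgery_cost + (costs.molecular_test_cost if trajectory.tested else 0.0)
    for t, stage, mask, event in zip(
        trajectory.times, trajectory.stages, trajectory.masks, trajectory.events
    ):
        d = (1.0 + r) ** (-t)
        w = 0.5 if event in DEATH_EVENT_NAMES else 1.0
        wdt = w * dt
        util = stage_util[stage]
        ann = 0.0
        for i in range(6):
            if mask & (1 << i):
                util *= ae_mult[i]
                ann += ae_ann[i]
        ly += wdt
        ly_d += d * wdt
        qaly += d * wdt * util
        c_bg += d * wdt * costs.background_annual_cost
        c_ae += d * wdt * ann
        if event in ae_acute:
            c_ae += d * ae_acute[event]
    for t_ev, kind in trajectory.treatments:
        d = (1.0 + r) ** (-t_ev)
        c_plgg += d * (costs.rt_course_cost if kind == "rt" else costs.chemo_course_cost)
    return OutcomeSummary(
        life_years=ly_d,
        qalys=qaly,
        cost_plgg=c_plgg,
        cost_ae=c_ae,
        cost_background=c_bg,
        cost_total=c_plgg + c_ae + c_bg,
        life_years_undiscounted=ly,
    )


def summarize_arm(result: ArmResult) -> OutcomeSummary:
    """Per-patient means of an arm run (first-order uncertainty not included)."""
    return OutcomeSummary(
        life_years=float(result.life_years.mean()),
        qalys=float(result.qalys.mean()),
        cost_plgg=float(result.cost_plgg.mean()),
        cost_ae=float(result.cost_ae.mean()),
        cost_background=float(result.cost_background.mean()),
        cost_total=float(
            result.cost_plgg.mean() + result.cost_ae.mean() + result.cost_background.mean()
        ),
        life_years_undiscounted=float(result.life_years_undiscounted.mean()),
    )


_EVENT_CLASSES = ("death", "progression") + AE_CLASSES


def _event_times(source, event_class: str) -> tuple[np.ndarray, float, int]:
    """(event times with NaN for censored, cycle length, n) from either an
    ArmResult or a sequence of Trajectory objects."""
    if event_class not in _EVENT_CLASSES:
        raise ValueError(f"unknown event class {event_class!r}; expected one of {_EVENT_CLASSES}")
    if isinstance(source, ArmResult):
        if event_class == "death":
            times = source.death_time
        elif event_class == "progression":
            times = source.first_progression_time
        else:
            times = source.ae_onset_time[:, AE_CLASSES.index(event_class)]
        return np.asarray(times, dtype=float), source.scenario.cycle_length, source.n
    trajectories = list(source)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    dt = trajectories[0].cycle_length
    out = []
    for tr in trajectories:
        if event_class == "death":
            out.append(tr.death_time if tr.death_time is not None else np.nan)
        elif event_class == "progression":
            out.append(
                tr.first_progression_time if tr.first_progression_time is not None else np.nan
            )
        else:
            out.append(tr.ae_onset_times.get(event_class, np.nan))
    return np.array(out, dtype=float), dt, len(trajectories)


def cumulative_incidence(source, event_class: str, horizon: float | None = None) -> pd.DataFrame:
    """Fraction of the cohort with the event by each cycle-grid time.

    Returns a DataFrame with columns ``time`` and ``fraction``; the curve is
    a non-decreasing step function in [0, 1] evaluated at t = 0, dt, 2*dt...
    """
    times, dt, n = _event_times(source, event_class)
    finite = times[np.isfinite(times)]
    if horizon is None:
        horizon = float(finite.max()) if finite.size else dt
    grid = np.arange(0.0, horizon + dt / 2, dt)
    frac = (finite[None, :] <= grid[:, None] + 1e-12).sum(axis=1) / n
    return pd.DataFrame({"time": grid, "fraction": frac})


def incidence_difference(intervention: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Pointwise (intervention - control) difference on the shared grid."""
    merged = intervention.merge(control, on="time", suffixes=("_i", "_c"))
    merged["difference"] = merged["fraction_i"] - merged["fraction_c"]
    return merged[["time", "difference"]]


@dataclass(frozen=True)
class StrategyComparison:
    """Incremental outcomes of testing vs no testing (intervention - control)."""

    delta_life_years: float
    delta_qalys: float
    delta_cost_total: float
    delta_cost_plgg: float
    delta_cost_ae: float
    delta_cost_background: float
    decision_change_fraction: float
    nnt_to_change_decision: float | None  # None when no decision changes
    dominance: str  # dominant / dominated / trade_off_NE / trade_off_SW / indifferent
    intervals: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        is_dominant = self.delta_qalys > 0 and self.delta_cost_total < 0
        if (self.dominance == "dominant") != is_dominant:
            raise ValueError("dominance class inconsistent with delta signs")


def classify_dominance(delta_qalys: float, delta_cost: float) -> str:
    if delta_qalys > 0 and delta_cost < 0:
        return "dominant"
    if delta_qalys < 0 and delta_cost > 0:
        return "dominated"
    if delta_qalys == 0 and delta_cost == 0:
        return "indifferent"
    if delta_cost >= 0:
        return "trade_off_NE"
    return "trade_off_SW"


def compare_strategies(intervention: ArmResult, control: ArmResult) -> StrategyComparison:
    """Per-patient mean deltas and the number needed to test.

    Both arms must have been run on the same cohort (common random numbers).
    The NNT is the reciprocal of the fraction of (tested) patients whose RT
    decision differs between arms; with no decision changes it is undefined
    and reported as None.
    """
    if intervention.n != control.n:
        raise ValueError(
            f"cohort sizes differ: {intervention.n} vs {control.n}; "
            "arms must share one cohort"
        )
    changed = (intervention.decision == 1) != (control.decision == 1)
    frac = float(changed.mean())
    dq = float(intervention.qalys.mean() - control.qalys.mean())
    dc = float(intervention.cost_total.mean() - control.cost_total.mean())
    return StrategyComparison(
        delta_life_years=float(intervention.life_years.mean() - control.life_years.mean()),
        delta_qalys=dq,
        delta_cost_total=dc,
        delta_cost_plgg=float(intervention.cost_plgg.mean() - control.cost_plgg.mean()),
        delta_cost_ae=float(intervention.cost_ae.mean() - control.cost_ae.mean()),
        delta_cost_background=float(
            intervention.cost_background.mean() - control.cost_background.mean()
        ),
        decision_change_fraction=frac,
        nnt_to_change_decision=(1.0 / frac) if frac > 0 else None,
        dominance=classify_dominance(dq, dc),
    )


def comparison_table(
    intervention: OutcomeSummary, control: OutcomeSummary, comparison: StrategyComparison
) -> pd.DataFrame:
    """Summary table: rows LY/QALY/costs, columns Intervention/Control/Delta."""
    rows = {
        "life_years": (intervention.life_years, control.life_years, comparison.delta_life_years),
        "qalys": (intervention.qalys, control.qalys, comparison.delta_qalys),
        "cost_total": (intervention.cost_total, control.cost_total, comparison.delta_cost_total),
        "cost_plgg": (intervention.cost_plgg, control.cost_plgg, comparison.delta_cost_plgg),
        "cost_ae": (intervention.cost_ae, control.cost_ae, comparison.delta_cost_ae),
        "cost_background": (
            intervention.cost_background,
            control.cost_background,
            comparison.delta_cost_background,
        ),
    }
    return pd.DataFrame(rows, index=["intervention", "control", "delta"]).T
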