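"""Probabilistic sensitivity analysis (PSA).

Model inputs are resampled from conventional uncertainty families — hazards
multiplicatively log-normal, utilities logit-normal (truncated to [0, 1] by
construction), costs gamma with fixed coefficient of variation — and the
full two-arm comparison is rerun per draw. The cohort and the trajectory
uniform stream are held fixed across runs (common random numbers), so the
resulting percentile intervals isolate parameter uncertainty; first-order
Monte-Carlo error is reported separately as the patient-level standard
error of the point-estimate run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import ComparisonBundle, ModelInputs, run_comparison
from .cohort import AE_CLASSES, CohortParams, generate_cohort
from .hazards import scale_hazards
from .strategies import ScenarioConfig
from .tables import UtilityTable


@dataclass(frozen=True)
class UncertaintySpec:
    """Spread per parameter block (0 disables sampling for that block).

    ``hazard_log_sd``: SD of the log-normal multiplier on each hazard block;
    ``utility_logit_sd``: SD of the normal shift on the logit of each
    utility/multiplier (boundary values 0 and 1 are structural and stay
    fixed); ``cost_cv``: coefficient of variation of the gamma draw around
    each mean cost.
    """

    hazard_log_sd: float = 0.1
    utility_logit_sd: float = 0.1
    cost_cv: float = 0.1

    def __post_init__(self) -> None:
        for name in ("hazard_log_sd", "utility_logit_sd", "cost_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @staticmethod
    def utility_only(utility_logit_sd: float = 0.1) -> "UncertaintySpec":
        """Uncertainty restricted to utility inputs (the published scope)."""
        return UncertaintySpec(hazard_log_sd=0.0, utility_logit_sd=utility_logit_sd, cost_cv=0.0)

    @staticmethod
    def none() -> "UncertaintySpec":
        return UncertaintySpec(0.0, 0.0, 0.0)


def _logit_normal(u: float, sd: float, rng: np.random.Generator) -> float:
    if u <= 0.0 or u >= 1.0:
        return u  # boundary utilities (e.g. dead = 0) are structural
    z = np.log(u / (1.0 - u)) + sd * rng.standard_normal()
    return float(1.0 / (1.0 + np.exp(-z)))


def _gamma(mean: float, cv: float, rng: np.random.Generator) -> float:
    if mean == 0.0:
        return 0.0
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def sample_inputs(base: ModelInputs, spec: UncertaintySpec, run_seed: int) -> ModelInputs:
    """One perturbed input set, deterministic given ``run_seed``.

    Zero spreads return the base objects unchanged (bit-identical).
    """
    rng = np.random.default_rng(run_seed)
    hazards = base.hazards
    if spec.hazard_log_sd > 0:
        mults = np.exp(spec.hazard_log_sd * rng.standard_normal(5))
        hazards = scale_hazards(
            hazards,
            progression=float(mults[0]),
            plgg_death=float(mults[1]),
            ae_excess=float(mults[2]),
            ae_baseline=float(mults[3]),
            background=float(mults[4]),
        )
    utilities = base.utilities
    if spec.utility_logit_sd > 0:
        utilities = UtilityTable(
            baseline_utility={
                k: _logit_normal(v, spec.utility_logit_sd, rng)
                for k, v in base.utilities.baseline_utility.items()
            },
            ae_utility_multiplier={
                k: _logit_normal(v, spec.utility_logit_sd, rng)
                for k, v in base.utilities.ae_utility_multiplier.items()
            },
        )
    costs = base.costs
    if spec.cost_cv > 0:
        costs = replace(
            costs,
            surgery_cost=_gamma(costs.surgery_cost, spec.cost_cv, rng),
            chemo_course_cost=_gamma(costs.chemo_course_cost, spec.cost_cv, rng),
            rt_course_cost=_gamma(costs.rt_course_cost, spec.cost_cv, rng),
            molecular_test_cost=_gamma(costs.molecular_test_cost, spec.cost_cv, rng),
            background_annual_cost=_gamma(costs.background_annual_cost, spec.cost_cv, rng),
            ae_annual_cost={
                c: _gamma(costs.ae_annual_cost[c], spec.cost_cv, rng) for c in AE_CLASSES
            },
            ae_acute_cost={
                c: _gamma(costs.ae_acute_cost[c], spec.cost_cv, rng) for c in AE_CLASSES
            },
        )
    return ModelInputs(hazards=hazards, costs=costs, utilities=utilities)


@dataclass
class PSARun:
    """One probabilistic draw: perturbed inputs and the resulting deltas."""

    run_id: int
    inputs: ModelInputs
    bundle: ComparisonBundle

    @property
    def delta_cost(self) -> float:
        return self.bundle.comparison.delta_cost_total

    @property
    def delta_qaly(self) -> float:
        return self.bundle.comparison.delta_qalys


def ci_percentile(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval (linear interpolation between order
    statistics, numpy's default). ``level`` 0 collapses to the median."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    if not 0.0 <= level < 1.0:
        raise ValueError(f"level must be in [0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


#: Outcome fields tracked per run in the PSA table.
_PSA_FIELDS = (
    "delta_qalys",
    "delta_cost_total",
    "delta_life_years",
    "delta_cost_plgg",
    "delta_cost_ae",
)
_ARM_FIELDS = ("life_years", "qalys", "cost_total", "cost_plgg", "cost_ae", "cost_background")


@dataclass
class PSAResult:
    """All runs plus percentile intervals and the fixed-input point estimate."""

    runs: pd.DataFrame  # one row per run (the cost-effectiveness plane data)
    intervals: dict[str, tuple[float, float]]
    point: ComparisonBundle  # zero-spread evaluation at the base inputs
    monte_carlo_se: dict[str, float]  # patient-level SE of the point run

    def ce_plane(self) -> pd.DataFrame:
        return self.runs[["run", "delta_qalys", "delta_cost_total"]].rename(
            columns={"delta_qalys": "delta_qaly", "delta_cost_total": "delta_cost"}
        )


def run_psa(
    cohort_params: CohortParams,
    base_inputs: ModelInputs,
    scenario: ScenarioConfig,
    uncertainty: UncertaintySpec,
    *,
    n_runs: int = 1000,
    master_seed: int = 0,
    level: float = 0.95,
) -> PSAResult:
    """Probabilistic sensitivity analysis over ``n_runs`` parameter draws.

    Each run perturbs the inputs, then reruns both arms on the *same* cohort
    and uniform stream (derived once from ``master_seed``), so run-to-run
    variation reflects parameters only. Reproducible from ``master_seed``.
    The per-run cohort size is ``cohort_params.n_patients``; desk-scale
    analyses use 1,000-10,000 patients per run.
    """
    if n_runs < 2:
        raise ValueError(f"n_runs must be >= 2, got {n_runs}")
    root = np.random.SeedSequence(master_seed)
    cohort_seed, traj_seed = (int(s) % 2**31 for s in root.generate_state(2))
    cohort = generate_cohort(replace(cohort_params, seed=cohort_seed))
    point = run_comparison(cohort, base_inputs, scenario, traj_seed=traj_seed)

    run_seeds = [int(s) % 2**31 for s in root.spawn(1)[0].generate_state(n_runs)]
    rows = []
    for i in range(n_runs):
        inputs_i = sample_inputs(base_inputs, uncertainty, run_seeds[i])
        bundle = run_comparison(cohort, inputs_i, scenario, traj_seed=traj_seed)
        comp = bundle.comparison
        row = {"run": i}
        for f in _PSA_FIELDS:
            row[f] = getattr(comp, f)
        for arm_name, summary in (
            ("testing", bundle.testing_summary),
            ("control", bundle.no_testing_summary),
        ):
            for f in _ARM_FIELDS:
                row[f"{arm_name}_{f}"] = getattr(summary, f)
        rows.append(row)
    runs = pd.DataFrame(rows)
    intervals = {
        c: ci_percentile(runs[c].to_numpy(), level) for c in runs.columns if c != "run"
    }
    n = point.testing.n
    mc_se = {
        "delta_qalys": float((point.testing.qalys - point.no_testing.qalys).std(ddof=1))
        / n**0.5,
        "delta_cost_total": float(
            (point.testing.cost_total - point.no_testing.cost_total).std(ddof=1)
        )
        / n**0.5,
    }
    return PSAResult(runs=runs, intervals=intervals, point=point, monte_carlo_se=mc_se)
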