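"""Orchestration: run strategy arms on a shared cohort and compare them."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .cohort import CohortParams, PatientRecord, generate_cohort
from .engine import ArmResult, simulate_cohort
from .hazards import HazardModel, build_hazard_model
from .outcomes import (
    OutcomeSummary,
    StrategyComparison,
    compare_strategies,
    summarize_arm,
)
from .strategies import ScenarioConfig
from .tables import CostTable, UtilityTable, default_cost_utility_tables


@dataclass(frozen=True)
class ModelInputs:
    """The complete parameter set of one model evaluation."""

    hazards: HazardModel
    costs: CostTable
    utilities: UtilityTable

    @staticmethod
    def default() -> "ModelInputs":
        costs, utilities = default_cost_utility_tables()
        return ModelInputs(hazards=build_hazard_model(), costs=costs, utilities=utilities)


@dataclass
class ComparisonBundle:
    """Both arms run under common random numbers, plus their comparison."""

    testing: ArmResult
    no_testing: ArmResult
    comparison: StrategyComparison

    @property
    def testing_summary(self) -> OutcomeSummary:
        return summarize_arm(self.testing)

    @property
    def no_testing_summary(self) -> OutcomeSummary:
        return summarize_arm(self.no_testing)


def run_arm(
    cohort: list[PatientRecord],
    inputs: ModelInputs,
    scenario: ScenarioConfig,
    *,
    traj_seed: int,
    record_states: bool = False,
    horizon: float | None = None,
) -> ArmResult:
    return simulate_cohort(
        cohort,
        inputs.hazards,
        scenario,
        inputs.costs,
        inputs.utilities,
        seed=traj_seed,
        record_states=record_states,
        horizon=horizon,
    )


def run_comparison(
    cohort: list[PatientRecord] | CohortParams,
    inputs: ModelInputs,
    scenario: ScenarioConfig,
    *,
    traj_seed: int,
) -> ComparisonBundle:
    """Run testing and no-testing arms on one cohort with a shared uniform
    stream (common random numbers) and compare them.

    ``scenario.arm`` is ignored; both arms are run.
    """
    if isinstance(cohort, CohortParams):
        cohort = generate_cohort(cohort)
    testing = run_arm(cohort, inputs, replace(scenario, arm="testing"), traj_seed=traj_seed)
    control = run_arm(cohort, inputs, replace(scenario, arm="no_testing"), traj_seed=traj_seed)
    return ComparisonBundle(
        testing=testing,
        no_testing=control,
        comparison=compare_strategies(testing, control),
    )


def null_scenario_inputs(inputs: ModelInputs) -> ModelInputs:
    """Inputs for the null (no-RT-effect) identity check.

    With the AE multiplier at 0 and the RT benefit off, arms differ only in
    which payoffs attach to the (state-identical) trajectories: the test cost
    and the RT-vs-chemo course substitution at first progression. Zeroing
    the test cost and equalizing the two course costs makes the arms exactly
    interchangeable, which is the contract this configuration encodes.
    """
    return replace(
        inputs,
        costs=replace(
            inputs.costs,
            molecular_test_cost=0.0,
            rt_course_cost=inputs.costs.chemo_course_cost,
        ),
    )
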