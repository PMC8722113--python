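import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plggsim import (
    CohortParams,
    PatientRecord,
    ScenarioConfig,
    accrue,
    combined_utility,
    compare_strategies,
    cumulative_incidence,
    default_cost_utility_tables,
    discount_factor,
    generate_cohort,
    simulate_cohort,
    simulate_trajectory,
    summarize_arm,
)
from plggsim.outcomes import OutcomeSummary, classify_dominance, incidence_difference
from plggsim.markov import expected_occupancy_markov

from conftest import make_hazards, zero_hazards


class TestDiscountFactor:
    def test_closed_form(self):
        assert discount_factor(1.0, 0.015) * 1.015 == pytest.approx(1.0, abs=1e-12)

    def test_zero_rate_and_present_value(self):
        assert discount_factor(17.0, 0.0) == 1.0
        assert discount_factor(0.0, 0.05) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1.0, 0.015)


class TestCombinedUtility:
    def test_identity_and_product(self):
        assert combined_utility(0.9, []) == 0.9
        assert combined_utility(0.9, [0.8]) == pytest.approx(0.72)

    def test_zero_annihilates(self):
        assert combined_utility(0.9, [0.0, 0.8]) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combined_utility(1.1, [])
        with pytest.raises(ValueError):
            combined_utility(0.9, [-0.1])

    @given(
        base=st.floats(min_value=0, max_value=1),
        mults=st.lists(st.floats(min_value=0, max_value=1), max_size=6),
    )
    def test_never_exceeds_any_input(self, base, mults):
        u = combined_utility(base, mults)
        assert 0.0 <= u <= min([base] + mults)


class TestAccrue:
    def test_death_in_first_cycle_credits_half_cycle(self, patient):
        costs, utils = default_cost_utility_tables(
            overrides={
                "baseline_utility": {"pre_progression": 1.0, "first_progression": 1.0,
                                     "later_progression": 1.0},
            }
        )
        traj = simulate_trajectory(patient, make_hazards(plgg_death=1e9), ScenarioConfig(), rng=0)
        s = accrue(traj, costs, utils, r=0.0)
        assert s.life_years == pytest.approx(0.5)
        assert s.qalys == pytest.approx(0.5)

    def test_unit_utilities_make_qaly_equal_ly(self, patient, inputs):
        costs, utils = default_cost_utility_tables(
            overrides={
                "baseline_utility": {"pre_progression": 1.0, "first_progression": 1.0,
                                     "later_progression": 1.0},
                "ae_utility_multiplier": {c: 1.0 for c in
                                          ("neurological", "auditory", "visual", "stroke",
                                           "cardiovascular", "secondary_neoplasm")},
            }
        )
        traj = simulate_trajectory(patient, inputs.hazards, ScenarioConfig(), rng=42)
        s = accrue(traj, costs, utils, r=0.0)
        assert s.qalys == pytest.approx(s.life_years, abs=1e-12)

    def test_zero_costs_give_zero_total(self, patient, inputs):
        costs, utils = default_cost_utility_tables(
            overrides={
                "surgery_cost": 0.0, "chemo_course_cost": 0.0, "rt_course_cost": 0.0,
                "molecular_test_cost": 0.0, "background_annual_cost": 0.0,
                "ae_annual_cost": {c: 0.0 for c in
                                   ("neurological", "auditory", "visual", "stroke",
                                    "cardiovascular", "secondary_neoplasm")},
                "ae_acute_cost": {c: 0.0 for c in
                                  ("neurological", "auditory", "visual", "stroke",
                                   "cardiovascular", "secondary_neoplasm")},
            }
        )
        traj = simulate_trajectory(patient, inputs.hazards, ScenarioConfig(), rng=42)
        s = accrue(traj, costs, utils, r=0.015)
        assert s.cost_total == 0.0

    def test_discounting_shrinks_payoffs(self, patient, inputs):
        traj = simulate_trajectory(patient, inputs.hazards, ScenarioConfig(), rng=1)
        s0 = accrue(traj, inputs.costs, inputs.utilities, r=0.0)
        s = accrue(traj, inputs.costs, inputs.utilities, r=0.015)
        assert s.life_years < s0.life_years
        assert s.cost_total < s0.cost_total

    def test_cost_additivity_and_qaly_bound_at_cohort_scale(self, inputs):
        cohort = generate_cohort(CohortParams(n_patients=2000, seed=4))
        res = simulate_cohort(
            cohort, inputs.hazards, ScenarioConfig(arm="no_testing", ae_multiplier=1.0),
            inputs.costs, inputs.utilities, seed=2,
        )
        np.testing.assert_allclose(
            res.cost_total, res.cost_plgg + res.cost_ae + res.cost_background, rtol=0, atol=1e-9
        )
        assert (res.qalys <= res.life_years + 1e-9).all()
        summary = summarize_arm(res)  # invariants re-checked in constructor
        assert summary.cost_total > 0


class TestOutcomeSummaryInvariants:
    def test_qaly_above_ly_rejected(self):
        with pytest.raises(ValueError, match="QALY"):
            OutcomeSummary(
                life_years=1.0, qalys=2.0, cost_plgg=0, cost_ae=0,
                cost_background=0, cost_total=0,
            )

    def test_non_additive_costs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            OutcomeSummary(
                life_years=1.0, qalys=0.5, cost_plgg=1.0, cost_ae=1.0,
                cost_background=0.0, cost_total=3.0,
            )


class TestCumulativeIncidence:
    def test_no_events_flat_zero(self, patient):
        trajs = [
            simulate_trajectory(patient, zero_hazards(), ScenarioConfig(), rng=i)
            for i in range(5)
        ]
        curve = cumulative_incidence(trajs, "death", horizon=20.0)
        assert (curve["fraction"] == 0.0).all()

    def test_universal_first_cycle_death_jumps_to_one(self, patient):
        trajs = [
            simulate_trajectory(patient, make_hazards(plgg_death=1e9), ScenarioConfig(), rng=i)
            for i in range(5)
        ]
        curve = cumulative_incidence(trajs, "death", horizon=3.0)
        assert curve.loc[curve["time"] == 0.0, "fraction"].item() == 0.0
        assert curve.loc[curve["time"] == 1.0, "fraction"].item() == 1.0

    def test_monotone_and_bounded(self, inputs):
        cohort = generate_cohort(CohortParams(n_patients=1000, seed=6))
        res = simulate_cohort(
            cohort, inputs.hazards, ScenarioConfig(arm="no_testing"),
            inputs.costs, inputs.utilities, seed=3,
        )
        for event in ("death", "progression", "stroke"):
            curve = cumulative_incidence(res, event, horizon=90.0)
            frac = curve["fraction"].to_numpy()
            assert (np.diff(frac) >= 0).all()
            assert frac.min() >= 0 and frac.max() <= 1

    def test_mortality_curve_matches_markov_survivor_fraction(self, inputs):
        profile = PatientRecord(
            id=0, age_at_dx=8.0, sex="female", fusion="non_fused",
            unresectable=True, measurable_disease=True, chemo_courses=1,
        )
        from plggsim.cohort import replicate_profile

        sc = ScenarioConfig(arm="no_testing", ae_multiplier=1.0)
        n = 4000
        res = simulate_cohort(
            replicate_profile(profile, n), inputs.hazards, sc,
            inputs.costs, inputs.utilities, seed=12, horizon=30,
        )
        curve = cumulative_incidence(res, "death", horizon=30.0)
        occ = expected_occupancy_markov(inputs.hazards, sc, profile, horizon=30)
        dead = 1.0 - occ.survival()
        for k in (10, 20, 30):
            p = dead[k]
            se = math.sqrt(p * (1 - p) / n)
            assert abs(curve.loc[curve["time"] == float(k), "fraction"].item() - p) < 3 * se + 4 / n

    def test_unknown_event_class_rejected(self, inputs):
        cohort = generate_cohort(CohortParams(n_patients=10, seed=1))
        res = simulate_cohort(
            cohort, inputs.hazards, ScenarioConfig(), inputs.costs, inputs.utilities, seed=1
        )
        with pytest.raises(ValueError, match="unknown event class"):
            cumulative_incidence(res, "relapse")

    def test_difference_curve_on_shared_grid(self, inputs):
        cohort = generate_cohort(CohortParams(n_patients=500, seed=2))
        sc = ScenarioConfig()
        a = simulate_cohort(cohort, inputs.hazards, sc, inputs.costs, inputs.utilities, seed=4)
        b = simulate_cohort(
            cohort, inputs.hazards, replace(sc, arm="no_testing"),
            inputs.costs, inputs.utilities, seed=4,
        )
        diff = incidence_difference(
            cumulative_incidence(a, "death", horizon=50.0),
            cumulative_incidence(b, "death", horizon=50.0),
        )
        assert len(diff) == 51
        assert diff["difference"].abs().max() <= 1.0


class TestCompareStrategies:
    @staticmethod
    def _fake_arm(decisions, qaly=10.0, cost=100.0):
        from plggsim.engine import ArmResult

        n = len(decisions)
        z = np.zeros(n)
        return ArmResult(
            arm="testing", scenario=ScenarioConfig(), n=n,
            life_years=np.full(n, 20.0), life_years_undiscounted=np.full(n, 30.0),
            qalys=np.full(n, qaly), cost_plgg=np.full(n, cost), cost_ae=z.copy(),
            cost_background=z.copy(), death_time=z.copy(), first_progression_time=z.copy(),
            ae_onset_time=np.zeros((n, 6)), decision=np.array(decisions, dtype=np.int8),
            rt_received=np.zeros(n, bool), n_progressions=np.zeros(n, int), tested=True,
        )

    def test_nnt_is_reciprocal_of_change_fraction(self):
        a = self._fake_arm([2, 2, 0, 0], qaly=11.0, cost=90.0)
        b = self._fake_arm([1, 1, 0, 0])
        comp = compare_strategies(a, b)
        assert comp.decision_change_fraction == 0.5
        assert comp.nnt_to_change_decision == 2.0
        assert comp.dominance == "dominant"

    def test_nnt_ten_for_ten_percent_change(self):
        a = self._fake_arm([2] + [0] * 9)
        b = self._fake_arm([1] + [0] * 9)
        assert compare_strategies(a, b).nnt_to_change_decision == 10.0

    def test_identical_arms_yield_null_comparison(self):
        a = self._fake_arm([0, 0])
        comp = compare_strategies(a, self._fake_arm([0, 0]))
        assert comp.delta_qalys == 0.0 and comp.delta_cost_total == 0.0
        assert comp.nnt_to_change_decision is None
        assert comp.dominance == "indifferent"

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="cohort sizes"):
            compare_strategies(self._fake_arm([0]), self._fake_arm([0, 0]))

    @pytest.mark.parametrize(
        "dq,dc,expected",
        [
            (0.5, -10.0, "dominant"),
            (-0.5, 10.0, "dominated"),
            (0.5, 10.0, "trade_off_NE"),
            (-0.5, -10.0, "trade_off_SW"),
        ],
    )
    def test_dominance_classification(self, dq, dc, expected):
        assert classify_dominance(dq, dc) == expected
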