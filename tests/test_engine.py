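import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plggsim import (
    ScenarioConfig,
    accrue,
    cycle_event_probabilities,
    hazard_to_prob,
    simulate_cohort,
    simulate_trajectory,
)
from plggsim.cohort import AE_CLASSES, generate_cohort, CohortParams
from plggsim.engine import DEATH_EVENT_NAMES

from conftest import make_hazards, zero_hazards


class TestHazardToProb:
    def test_null_rate(self):
        assert hazard_to_prob(0.0, 1.0) == 0.0

    def test_half_life(self):
        assert hazard_to_prob(math.log(2), 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_against_series_expansion_oracle(self):
        # oracle: 1 - exp(-x) = x - x^2/2! + x^3/3! - ... for small x
        x = 0.06673
        series = sum((-1) ** (k + 1) * x**k / math.factorial(k) for k in range(1, 12))
        assert hazard_to_prob(x, 1.0) == pytest.approx(series, abs=1e-14)
        assert hazard_to_prob(x, 1.0) == pytest.approx(0.06455, abs=5e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            hazard_to_prob(-0.1, 1.0)


class TestCycleEventProbabilities:
    def test_dead_patient_rejected(self, patient, inputs):
        patient.alive = False
        with pytest.raises(ValueError, match="dead"):
            cycle_event_probabilities(patient, inputs.hazards, ScenarioConfig())

    def test_all_flags_set_offers_no_onsets(self, patient, inputs):
        patient.ae_flags = set(AE_CLASSES)
        patient.n_progressions = 1
        probs = cycle_event_probabilities(patient, inputs.hazards, ScenarioConfig())
        assert not any(k.startswith("ae_onset_") for k in probs)
        assert {"ae_death_stroke", "ae_death_cardiovascular", "ae_death_secondary_neoplasm"} <= set(
            probs
        )

    def test_multiplier_scales_rt_excess_only(self, patient, inputs):
        lo = cycle_event_probabilities(
            patient, inputs.hazards, ScenarioConfig(ae_multiplier=0.5)
        )
        hi = cycle_event_probabilities(
            patient, inputs.hazards, ScenarioConfig(ae_multiplier=1.0)
        )
        assert lo == hi  # patient never irradiated

    def test_zero_hazards_conserve_everything(self, patient):
        probs = cycle_event_probabilities(patient, zero_hazards(), ScenarioConfig())
        assert probs["none"] == 1.0
        assert all(p == 0.0 for k, p in probs.items() if k != "none")

    @given(
        prog=st.floats(min_value=0, max_value=2),
        death=st.floats(min_value=0, max_value=2),
        mult=st.floats(min_value=0, max_value=1),
        nprog=st.integers(min_value=0, max_value=3),
        flags=st.sets(st.sampled_from(AE_CLASSES)),
    )
    def test_probability_conservation_property(self, prog, death, mult, nprog, flags):
        from plggsim import PatientRecord

        patient = PatientRecord(
            id=0, age_at_dx=8.0, sex="female", fusion="non_fused",
            unresectable=True, measurable_disease=True, chemo_courses=1,
            ae_flags=flags, n_progressions=nprog, rt_received=nprog >= 1,
        )
        probs = cycle_event_probabilities(
            patient,
            make_hazards(progression=prog, plgg_death=death),
            ScenarioConfig(ae_multiplier=mult),
        )
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= p <= 1.0 for p in probs.values())


class TestSimulateTrajectory:
    def test_non_initial_patient_rejected(self, patient, inputs):
        patient.n_progressions = 2
        with pytest.raises(ValueError, match="initial"):
            simulate_trajectory(patient, inputs.hazards, ScenarioConfig(), rng=0)

    def test_immediate_death_dominance(self, patient):
        hz = make_hazards(plgg_death=1e9)
        traj = simulate_trajectory(patient, hz, ScenarioConfig(), rng=0)
        assert len(traj) == 1
        assert traj.terminal_cause == "plgg_death"
        assert traj.death_time == 1.0

    def test_null_dynamics_survive_to_age_cap(self, patient):
        traj = simulate_trajectory(patient, zero_hazards(), ScenarioConfig(), rng=0)
        assert traj.terminal_cause is None and traj.death_time is None
        assert len(traj) == math.ceil(100.0 - patient.age_at_dx)
        assert all(e is None for e in traj.events)

    def test_reproducible_given_seed(self, patient, inputs):
        t1 = simulate_trajectory(patient, inputs.hazards, ScenarioConfig(), rng=77)
        t2 = simulate_trajectory(patient, inputs.hazards, ScenarioConfig(), rng=77)
        assert t1.to_frame().equals(t2.to_frame())

    def test_monotone_history_and_absorbing_death(self, small_cohort, inputs):
        sc = ScenarioConfig(arm="no_testing", rt_benefit=True, ae_multiplier=1.0)
        for p in small_cohort[:100]:
            traj = simulate_trajectory(p, inputs.hazards, sc, rng=p.id)
            masks = traj.masks
            assert all(m1 & m0 == m0 for m0, m1 in zip(masks, masks[1:]))  # flags monotone
            death_cycles = [i for i, e in enumerate(traj.events) if e in DEATH_EVENT_NAMES]
            if death_cycles:
                assert death_cycles[0] == len(traj) - 1  # nothing after death
            progs = [e for e in traj.events if e == "progression"]
            assert traj.n_progressions == len(progs)
            if traj.rt_received:
                assert traj.decision == "give_rt"
                assert sum(1 for _, k in traj.treatments if k == "rt") == 1

    def test_state_labels_report_ae_onset_cycles(self, patient):
        hz = make_hazards(progression=0.0, plgg_death=0.0)
        traj = simulate_trajectory(patient, hz, ScenarioConfig(), rng=3)
        labels = traj.state_labels()
        for lbl, ev in zip(labels, traj.events):
            if ev is not None and ev.startswith("ae_onset_"):
                assert lbl == "ae_" + ev[len("ae_onset_"):]


class TestVectorizedEngineParity:
    def test_cohort_engine_matches_per_patient_path(self, inputs):
        """The vectorized engine and the per-patient loop must produce
        identical trajectories and payoffs given the same uniform stream."""
        cohort = generate_cohort(CohortParams(n_patients=150, seed=5))
        sc = ScenarioConfig(arm="testing", rt_benefit=True, ae_multiplier=0.6)
        seed = 31
        res = simulate_cohort(
            cohort, inputs.hazards, sc, inputs.costs, inputs.utilities, seed=seed
        )
        age0 = np.array([p.age_at_dx for p in cohort])
        n_cycles = max(1, math.ceil((sc.age_cap - age0.min()) / sc.cycle_length - 1e-9))
        U = np.random.Generator(np.random.Philox(seed)).random((len(cohort), n_cycles))
        for i, p in enumerate(cohort):
            traj = simulate_trajectory(p, inputs.hazards, sc, uniforms=U[i])
            summary = accrue(traj, inputs.costs, inputs.utilities, r=sc.discount_rate)
            assert summary.life_years == pytest.approx(res.life_years[i], rel=1e-12)
            assert summary.qalys == pytest.approx(res.qalys[i], rel=1e-12)
            assert summary.cost_plgg == pytest.approx(res.cost_plgg[i], rel=1e-12)
            assert summary.cost_ae == pytest.approx(res.cost_ae[i], rel=1e-12, abs=1e-9)
            assert summary.cost_background == pytest.approx(res.cost_background[i], rel=1e-12)
            assert traj.rt_received == res.rt_received[i]
            assert traj.n_progressions == res.n_progressions[i]

    def test_empty_cohort_rejected(self, inputs):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_cohort([], inputs.hazards, ScenarioConfig(), inputs.costs, inputs.utilities, seed=0)

    def test_common_random_numbers_null_coupling(self, inputs):
        """With AE multiplier 0 and no RT benefit, arms share every event."""
        cohort = generate_cohort(CohortParams(n_patients=400, seed=8))
        sc = ScenarioConfig(rt_benefit=False, ae_multiplier=0.0)
        a = simulate_cohort(
            cohort, inputs.hazards, replace(sc, arm="testing"),
            inputs.costs, inputs.utilities, seed=9,
        )
        b = simulate_cohort(
            cohort, inputs.hazards, replace(sc, arm="no_testing"),
            inputs.costs, inputs.utilities, seed=9,
        )
        assert np.array_equal(a.death_time, b.death_time, equal_nan=True)
        assert np.array_equal(a.ae_onset_time, b.ae_onset_time, equal_nan=True)
        assert np.array_equal(a.n_progressions, b.n_progressions)
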