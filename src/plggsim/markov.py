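"""Cohort-level Markov oracle for the microsimulation.

For a fixed representative patient profile, the per-cycle event
probabilities imply a (time-inhomogeneous) Markov chain over the expanded
state space

    disease stage {pre, first, later} x RT flag x 64 AE-flag combinations,
    plus the absorbing dead state

(385 states). Iterating its cycle-wise transition matrices gives exact
expected state occupancy, against which the stochastic microsimulation can
be checked at binomial-sampling accuracy. The matrix is assembled from the
same rate arithmetic the simulator uses, but through an independent
deterministic path (explicit matrix products rather than sampled events).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import AE_CLASSES, PatientRecord
from .engine import _AE_BITS, _event_rates
from .hazards import HazardModel
from .strategies import ScenarioConfig, apply_scenario, rt_eligible, treatment_decision

N_ALIVE = 3 * 2 * 64
N_STATES = N_ALIVE + 1
DEAD = N_ALIVE


def _sidx(stage: int, rt: bool, mask: int) -> int:
    return stage * 128 + int(rt) * 64 + mask


@dataclass
class MarkovOccupancy:
    """Expected occupancy fractions per cycle over the expanded state space.

    ``occupancy[k]`` is the distribution at the start of cycle k
    (``occupancy[0]`` is the initial state). Marginal views aggregate to the
    quantities the microsimulation records.
    """

    occupancy: np.ndarray  # (horizon+1, N_STATES)
    cycle_length: float

    def stage_occupancy(self) -> np.ndarray:
        """(horizon+1, 4): pre / first / later progression / dead."""
        out = np.zeros((self.occupancy.shape[0], 4))
        for stage in range(3):
            lo = stage * 128
            out[:, stage] = self.occupancy[:, lo : lo + 128].sum(axis=1)
        out[:, 3] = self.occupancy[:, DEAD]
        return out

    def ae_prevalence(self) -> np.ndarray:
        """(horizon+1, 6): fraction of the cohort alive with each AE flag set."""
        alive = self.occupancy[:, :N_ALIVE]
        masks = np.arange(N_ALIVE) % 64
        out = np.zeros((self.occupancy.shape[0], 6))
        for i, c in enumerate(AE_CLASSES):
            sel = (masks & _AE_BITS[c]) != 0
            out[:, i] = alive[:, sel].sum(axis=1)
        return out

    def survival(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD]


def transition_matrix(
    hazards: HazardModel,
    scenario: ScenarioConfig,
    profile: PatientRecord,
    cycle: int,
) -> np.ndarray:
    """The (N_STATES x N_STATES) one-cycle transition matrix at ``cycle``.

    Every row sums to 1 exactly (stay probability computed by complement).
    The RT decision at the pre -> first-progression transition is
    deterministic given the profile, the arm, and the attained age at the
    cycle in which the progression fires.
    """
    eff = apply_scenario(hazards, scenario)
    dt = scenario.cycle_length
    t = cycle * dt
    age = profile.age_at_dx + t
    arm = scenario.arm
    if arm == "testing":
        knowledge = "known_fused" if profile.fusion == "fused" else "known_non_fused"
    else:
        knowledge = "unknown"
    probe = PatientRecord(
        id=profile.id,
        age_at_dx=profile.age_at_dx,
        sex=profile.sex,
        fusion=profile.fusion,
        unresectable=profile.unresectable,
        measurable_disease=profile.measurable_disease,
        chemo_courses=profile.chemo_courses,
        time_since_dx=t,
        n_progressions=1,
    )
    rt_on_first_progression = (
        treatment_decision(probe, knowledge, rt_eligible(probe)) == "give_rt"
    )

    M = np.zeros((N_STATES, N_STATES))
    M[DEAD, DEAD] = 1.0
    for stage in range(3):
        for rt in (False, True):
            for mask in range(64):
                s = _sidx(stage, rt, mask)
                rates = _event_rates(profile.fusion, stage, rt, mask, age, t, eff)
                total = sum(r for _, r in rates)
                p_any = -math.expm1(-total * dt)
                scale = p_any / total if total > 0 else 0.0
                row_events = 0.0
                for name, r in rates:
                    p = r * scale
                    row_events += p
                    if name == "progression":
                        if stage == 0:
                            dest = _sidx(1, rt_on_first_progression, mask)
                        else:
                            dest = _sidx(2, rt, mask)
                    elif name.startswith("ae_onset_"):
                        c = name[len("ae_onset_"):]
                        dest = _sidx(stage, rt, mask | _AE_BITS[c])
                    else:  # any death
                        dest = DEAD
                    M[s, dest] += p
                M[s, s] += 1.0 - row_events
    return M


def expected_occupancy_markov(
    hazards: HazardModel,
    scenario: ScenarioConfig,
    profile: PatientRecord,
    horizon: int,
) -> MarkovOccupancy:
    """Iterate the cycle-wise transition matrices for ``horizon`` cycles."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, _sidx(0, False, 0)] = 1.0
    for k in range(horizon):
        M = transition_matrix(hazards, scenario, profile, k)
        occ[k + 1] = occ[k] @ M
    return MarkovOccupancy(occupancy=occ, cycle_length=scenario.cycle_length)
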