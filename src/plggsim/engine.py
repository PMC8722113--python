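"""The individual-level state-transition engine.

Each simulated patient advances in discrete cycles (default one year) from
diagnosis to death or an age cap. Disease stage moves through
pre-progression, first progression and later progression(s); six classes of
treatment-related adverse events (AEs) accumulate as concurrent flags on top
of the disease stage; death is absorbing. Within a cycle, competing events
are composed from independent hazards via a total-rate exponential draw with
the event type chosen proportional to its rate, so at most one event fires
per cycle and ordering is well-defined and unbiased.

Two equivalent execution paths exist: :func:`simulate_trajectory` runs one
patient through an explicit loop and returns a full per-cycle
:class:`Trajectory` (used for inspection and tests), and
:func:`simulate_cohort` runs a whole cohort column-wise over numpy arrays,
accruing discounted payoffs on the fly. Both consume one uniform per patient
per cycle from the same counter-based stream layout, so a patient's fate is
identical under either path and — by construction — across strategy arms and
scenarios sharing the seed (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AE_CLASSES, LETHAL_AE_CLASSES, PatientRecord
from .hazards import HazardModel
from .strategies import ScenarioConfig, apply_scenario, rt_eligible, treatment_decision
from .tables import CostTable, DISEASE_STAGES, UtilityTable

STAGE_CODES = {name: i for i, name in enumerate(DISEASE_STAGES)}

#: Canonical event order; the within-cycle draw resolves ties by this order.
EVENT_NAMES = (
    ("progression", "plgg_death", "background_death")
    + tuple(f"ae_onset_{c}" for c in AE_CLASSES)
    + tuple(f"ae_death_{c}" for c in LETHAL_AE_CLASSES)
)
N_EVENTS = len(EVENT_NAMES)
DEATH_EVENT_NAMES = frozenset(
    ("plgg_death", "background_death") + tuple(f"ae_death_{c}" for c in LETHAL_AE_CLASSES)
)
DEATH_EVENT_IDX = np.array(
    [i for i, n in enumerate(EVENT_NAMES) if n in DEATH_EVENT_NAMES], dtype=np.int64
)
_AE_BITS = {c: 1 << i for i, c in enumerate(AE_CLASSES)}
_LETHAL_IDX = [AE_CLASSES.index(c) for c in LETHAL_AE_CLASSES]


def hazard_to_prob(rate: float, dt: float) -> float:
    """Probability of at least one event in ``dt`` years at constant ``rate``."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return -math.expm1(-rate * dt)


def _event_rates(
    fusion: str,
    n_progressions: int,
    rt_received: bool,
    mask: int,
    age: float,
    t: float,
    eff: HazardModel,
) -> list[tuple[str, float]]:
    """Offered competing events and their per-year rates, canonical order.

    ``eff`` must already carry the scenario's RT hazard ratio and AE
    multiplier (see :func:`plggsim.strategies.apply_scenario`). AE onsets are
    offered only for classes not yet flagged; AE deaths only for active
    lethal flags.
    """
    rates = [
        ("progression", eff.progression_hazard(fusion, n_progressions, rt_received)),
        ("plgg_death", eff.plgg_death_hazard(fusion, n_progressions)),
        ("background_death", eff.background_mortality(age)),
    ]
    for c in AE_CLASSES:
        if not mask & _AE_BITS[c]:
            rates.append((f"ae_onset_{c}", eff.ae_hazard(c, t, rt_received)))
    for c in LETHAL_AE_CLASSES:
        if mask & _AE_BITS[c]:
            rates.append((f"ae_death_{c}", eff.ae_mortality_rate(c)))
    return rates


def cycle_event_probabilities(
    patient: PatientRecord, hazards: HazardModel, scenario: ScenarioConfig
) -> dict[str, float]:
    """Per-cycle probability of each offered event, plus ``"none"``.

    The probabilities and the stay probability sum to 1 (up to float
    round-off, < 1e-12). Rejects dead patients.
    """
    if not patient.alive:
        raise ValueError(f"patient {patient.id} is dead; no events can be offered")
    eff = apply_scenario(hazards, scenario)
    mask = 0
    for c in patient.ae_flags:
        mask |= _AE_BITS[c]
    rates = _event_rates(
        patient.fusion,
        patient.n_progressions,
        patient.rt_received,
        mask,
        patient.age,
        patient.time_since_dx,
        eff,
    )
    total = sum(r for _, r in rates)
    p_any = -math.expm1(-total * scenario.cycle_length)
    scale = p_any / total if total > 0 else 0.0
    probs = {name: r * scale for name, r in rates}
    probs["none"] = 1.0 - sum(probs.values())
    return probs


@dataclass
class Trajectory:
    """Per-cycle history of one simulated patient.

    ``times``/``stages``/``masks`` are the state at each cycle *start*;
    ``events`` holds the event (if any) fired during that cycle. Sparse
    event times (death, onsets, first progression) are recorded at the end
    of the cycle in which the event fired.
    """

    patient_id: int
    arm: str
    cycle_length: float
    tested: bool
    times: list[float] = field(default_factory=list)
    stages: list[int] = field(default_factory=list)
    masks: list[int] = field(default_factory=list)
    events: list[str | None] = field(default_factory=list)
    treatments: list[tuple[float, str]] = field(default_factory=list)  # (cycle start, kind)
    decision: str | None = None  # give_rt / give_chemo at first progression
    terminal_cause: str | None = None  # None if censored at the age cap
    death_time: float | None = None
    first_progression_time: float | None = None
    ae_onset_times: dict[str, float] = field(default_factory=dict)
    n_progressions: int = 0
    rt_received: bool = False

    def __len__(self) -> int:
        return len(self.times)

    def state_labels(self) -> list[str]:
        """Reported model-state label per cycle: the disease stage, except
        in a cycle where an AE onset fired, which reports that AE state."""
        labels = []
        for stage, event in zip(self.stages, self.events):
            if event is not None and event.startswith("ae_onset_"):
                labels.append("ae_" + event[len("ae_onset_"):])
            else:
                labels.append(DISEASE_STAGES[stage])
        return labels

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-cycle records with deterministic column order."""
        return pd.DataFrame(
            {
                "patient": self.patient_id,
                "cycle": range(len(self.times)),
                "time_since_dx": self.times,
                "stage": [DISEASE_STAGES[s] for s in self.stages],
                "state": self.state_labels(),
                "ae_flags": [
                    "|".join(c for c in AE_CLASSES if m & _AE_BITS[c]) for m in self.masks
                ],
                "event": [e if e is not None else "" for e in self.events],
            },
            columns=["patient", "cycle", "time_since_dx", "stage", "state", "ae_flags", "event"],
        )


def write_trajectories_csv(trajectories, path) -> None:
    pd.concat([t.to_frame() for t in trajectories], ignore_index=True).to_csv(path, index=False)


def simulate_trajectory(
    patient: PatientRecord,
    hazards: HazardModel,
    scenario: ScenarioConfig,
    rng: np.random.Generator | int | None = None,
    *,
    uniforms: np.ndarray | None = None,
    horizon: float | None = None,
) -> Trajectory:
    """Run one patient from diagnosis to death, the age cap, or ``horizon``.

    ``uniforms`` (one per cycle) pins the randomness explicitly — the
    vectorized cohort engine feeds each patient the corresponding row of its
    uniform matrix, making the two paths event-for-event identical.
    The input record is not mutated.
    """
    if not (
        patient.alive
        and patient.time_since_dx == 0.0
        and patient.n_progressions == 0
        and not patient.ae_flags
        and not patient.rt_received
    ):
        raise ValueError("patient must be in the initial pre-progression state")
    if uniforms is None:
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        draw = rng.random
    else:
        uniform_iter = iter(np.asarray(uniforms, dtype=float))

        def draw() -> float:
            return float(next(uniform_iter))

    eff = apply_scenario(hazards, scenario)
    dt = scenario.cycle_length
    arm = scenario.arm
    tested = arm == "testing"
    if tested:
        knowledge = "known_fused" if patient.fusion == "fused" else "known_non_fused"
    else:
        knowledge = "unknown"

    traj = Trajectory(patient.id, arm, dt, tested)
    age0 = patient.age_at_dx
    mask = 0
    stage = 0
    n_prog = 0
    rt = False
    chemo = patient.chemo_courses
    t = 0.0
    k = 0
    while True:
        if age0 + t >= scenario.age_cap - 1e-12:
            break
        if horizon is not None and t >= horizon - 1e-12:
            break
        rates = _event_rates(patient.fusion, n_prog, rt, mask, age0 + t, t, eff)
        total = sum(r for _, r in rates)
        p_any = -math.expm1(-total * dt)
        scale = p_any / total if total > 0 else 0.0
        u = draw()
        event: str | None = None
        acc = 0.0
        for name, r in rates:
            acc += r * scale
            if u < acc:
                event = name
                break
        traj.times.append(t)
        traj.stages.append(stage)
        traj.masks.append(mask)
        traj.events.append(event)

        if event == "progression":
            n_prog += 1
            if n_prog == 1:
                probe = PatientRecord(
                    id=patient.id,
                    age_at_dx=age0,
                    sex=patient.sex,
                    fusion=patient.fusion,
                    unresectable=patient.unresectable,
                    measurable_disease=patient.measurable_disease,
                    chemo_courses=chemo,
                    time_since_dx=t,
                    n_progressions=1,
                )
                decision = treatment_decision(probe, knowledge, rt_eligible(probe))
                traj.decision = decision
                traj.first_progression_time = t + dt
                if decision == "give_rt":
                    rt = True
                    traj.treatments.append((t, "rt"))
                else:
                    chemo += 1
                    traj.treatments.append((t, "chemo"))
                stage = 1
            else:
                chemo += 1
                traj.treatments.append((t, "chemo"))
                stage = 2
        elif event is not None and event.startswith("ae_onset_"):
            c = event[len("ae_onset_"):]
            mask |= _AE_BITS[c]
            traj.ae_onset_times[c] = t + dt
        elif event in DEATH_EVENT_NAMES:
            traj.terminal_cause = event
            traj.death_time = t + dt
            stage = 3
        t += dt
        k += 1
        if stage == 3:
            break
    traj.n_progressions = n_prog
    traj.rt_received = rt
    return traj


@dataclass
class ArmResult:
    """Per-patient outcomes of one strategy arm run on one cohort.

    All monetary and QALY fields are discounted to diagnosis; ``life_years``
    is discounted too (``life_years_undiscounted`` keeps the raw total).
    Event times are years since diagnosis (NaN if the event never fired).
    """

    arm: str
    scenario: ScenarioConfig
    n: int
    life_years: np.ndarray
    life_years_undiscounted: np.ndarray
    qalys: np.ndarray
    cost_plgg: np.ndarray
    cost_ae: np.ndarray
    cost_background: np.ndarray
    death_time: np.ndarray
    first_progression_time: np.ndarray
    ae_onset_time: np.ndarray  # (n, 6) in AE_CLASSES order
    decision: np.ndarray  # 0 none, 1 rt, 2 chemo
    rt_received: np.ndarray
    n_progressions: np.ndarray
    tested: bool
    stage_record: np.ndarray | None = None  # (n, cycles+1) stage at cycle start
    mask_record: np.ndarray | None = None

    @property
    def cost_total(self) -> np.ndarray:
        return self.cost_plgg + self.cost_ae + self.cost_background


def simulate_cohort(
    cohort: list[PatientRecord],
    hazards: HazardModel,
    scenario: ScenarioConfig,
    costs: CostTable,
    utilities: UtilityTable,
    *,
    seed: int,
    horizon: float | None = None,
    record_states: bool = False,
) -> ArmResult:
    """Vectorized cohort run: simulate every patient and accrue payoffs.

    ``seed`` keys the counter-based (Philox) uniform matrix with one row per
    patient and one column per cycle; re-using the seed across arms or
    scenarios yields common random numbers. Payoffs are discounted at cycle
    start with annual compounding; the death cycle credits half a cycle of
    life-years, QALYs and recurring costs.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort must be non-empty")
    eff = apply_scenario(hazards, scenario)
    dt = scenario.cycle_length
    r_disc = scenario.discount_rate
    arm = scenario.arm
    tested = arm == "testing"

    age0 = np.array([p.age_at_dx for p in cohort])
    fused = np.array([p.fusion == "fused" for p in cohort])
    unres = np.array([p.unresectable for p in cohort])
    meas = np.array([p.measurable_disease for p in cohort])
    chemo = np.array([p.chemo_courses for p in cohort], dtype=np.int64)

    max_t = horizon if horizon is not None else scenario.age_cap - float(age0.min())
    n_cycles = max(1, int(math.ceil(max_t / dt - 1e-9)))
    U = np.random.Generator(np.random.Philox(seed)).random((n, n_cycles))

    # per-(fusion, progressed) disease rates
    pr = np.where(fused, eff.progression_rate["fused"], eff.progression_rate["non_fused"])
    pdth = np.where(fused, eff.plgg_death_rate["fused"], eff.plgg_death_rate["non_fused"])
    ae_base = np.array([eff.ae[c].baseline_rate for c in AE_CLASSES])
    ae_exc = np.array([eff.ae[c].excess_rate for c in AE_CLASSES])
    ae_blat = np.array([eff.ae[c].baseline_latency for c in AE_CLASSES])
    ae_elat = np.array([eff.ae[c].excess_latency for c in AE_CLASSES])
    ae_mort = np.array([eff.ae_mortality[c] for c in LETHAL_AE_CLASSES])
    mult = eff.ae_excess_multiplier
    hr_rt = eff.rt_progression_hr

    # mask-indexed lookup tables over the 64 AE-flag combinations
    bits = (np.arange(64)[:, None] >> np.arange(6)[None, :]) & 1
    ae_umult = np.array([utilities.ae_utility_multiplier[c] for c in AE_CLASSES])
    mask_util = np.prod(np.where(bits == 1, ae_umult[None, :], 1.0), axis=1)
    ae_ann = np.array([costs.ae_annual_cost[c] for c in AE_CLASSES])
    mask_ann = bits @ ae_ann
    ae_acute = np.array([costs.ae_acute_cost[c] for c in AE_CLASSES])
    stage_util = np.array([utilities.baseline_utility[s] for s in DISEASE_STAGES])

    stage = np.zeros(n, dtype=np.int8)
    mask = np.zeros(n, dtype=np.int8)
    nprog = np.zeros(n, dtype=np.int64)
    rt = np.zeros(n, dtype=bool)
    decision = np.zeros(n, dtype=np.int8)

    ly = np.zeros(n)
    ly_d = np.zeros(n)
    qaly = np.zeros(n)
    c_plgg = np.full(n, costs.surgery_cost + (costs.molecular_test_cost if tested else 0.0))
    c_ae = np.zeros(n)
    c_bg = np.zeros(n)
    death_time = np.full(n, np.nan)
    first_prog_time = np.full(n, np.nan)
    ae_onset_time = np.full((n, 6), np.nan)

    if record_states:
        stage_rec = np.zeros((n, n_cycles + 1), dtype=np.int8)
        mask_rec = np.zeros((n, n_cycles + 1), dtype=np.int8)
    else:
        stage_rec = mask_rec = None

    lam = np.zeros((n, N_EVENTS))
    for k in range(n_cycles):
        t = k * dt
        if record_states:
            stage_rec[:, k] = stage
            mask_rec[:, k] = mask
        active = (stage < 3) & (age0 + t < scenario.age_cap - 1e-12)
        if not active.any():
            if record_states:
                stage_rec[:, k:] = stage[:, None]
                mask_rec[:, k:] = mask[:, None]
            break
        progressed = nprog >= 1
        lam[:, 0] = pr * np.where(progressed, eff.reprogression_hr, 1.0) * np.where(rt, hr_rt, 1.0)
        lam[:, 1] = pdth * np.where(progressed, eff.post_progression_death_hr, 1.0)
        lam[:, 2] = eff.background.rate_array(age0 + t)
        flagged = (mask[:, None] & (1 << np.arange(6))[None, :]) != 0
        onset = np.where(t >= ae_blat, ae_base, 0.0)[None, :] + (
            rt[:, None] * mult * np.where(t >= ae_elat, ae_exc, 0.0)[None, :]
        )
        lam[:, 3:9] = np.where(flagged, 0.0, onset)
        lam[:, 9:12] = np.where(flagged[:, _LETHAL_IDX], ae_mort[None, :], 0.0)
        lam *= active[:, None]

        total = lam.sum(axis=1)
        p_any = -np.expm1(-total * dt)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(total > 0, p_any / total, 0.0)
        cum = np.cumsum(lam * scale[:, None], axis=1)
        u = U[:, k]
        hit = u[:, None] < cum
        ev = np.where(hit[:, -1], hit.argmax(axis=1), -1)
        ev[~active] = -1

        # accrual for the state occupied at cycle start
        d = (1.0 + r_disc) ** (-t)
        death_ev = np.isin(ev, DEATH_EVENT_IDX)
        w = np.where(active, np.where(death_ev, 0.5, 1.0), 0.0)
        wdt = w * dt
        ly += wdt
        ly_d += d * wdt
        qaly += d * wdt * stage_util[stage] * mask_util[mask]
        c_bg += d * wdt * costs.background_annual_cost
        c_ae += d * wdt * mask_ann[mask]

        # apply events
        prog_ev = ev == 0
        if prog_ev.any():
            nprog[prog_ev] += 1
            first = prog_ev & (nprog == 1)
            age_now = age0 + t
            elig = (
                first
                & unres
                & meas
                & (age_now >= 3.0)
                & (age_now <= 21.0)
                & ((age_now >= 10.0) | (chemo >= 1))
            )
            give_rt = (elig & ~fused) if arm == "testing" else elig
            rt |= give_rt
            decision[first] = np.where(give_rt[first], 1, 2)
            chemo_now = prog_ev & ~give_rt
            chemo[chemo_now] += 1
            c_plgg += d * (give_rt * costs.rt_course_cost + chemo_now * costs.chemo_course_cost)
            first_prog_time[first] = t + dt
            stage[prog_ev] = np.where(nprog[prog_ev] == 1, 1, 2)
        for i in range(6):
            onset_i = ev == 3 + i
            if onset_i.any():
                mask[onset_i] |= 1 << i
                c_ae[onset_i] += d * ae_acute[i]
                ae_onset_time[onset_i, i] = t + dt
        if death_ev.any():
            stage[death_ev] = 3
            death_time[death_ev] = t + dt
    else:
        if record_states:
            stage_rec[:, n_cycles] = stage
            mask_rec[:, n_cycles] = mask

    return ArmResult(
        arm=arm,
        scenario=scenario,
        n=n,
        life_years=ly_d,
        life_years_undiscounted=ly,
        qalys=qaly,
        cost_plgg=c_plgg,
        cost_ae=c_ae,
        cost_background=c_bg,
        death_time=death_time,
        first_progression_time=first_prog_time,
        ae_onset_time=ae_onset_time,
        decision=decision,
        rt_received=rt,
        n_progressions=nprog,
        tested=tested,
        stage_record=stage_rec,
        mask_record=mask_rec,
    )
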