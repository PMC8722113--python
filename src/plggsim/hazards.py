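"""Hazard calibration for the PLGG state-transition model.

Disease transitions (progression, PLGG-related death) use constant
(exponential) hazards per fusion stratum, calibrated so that the cumulative
event probability at the cohort's mean follow-up time reproduces the
published event proportion exactly:

    lambda = -ln(1 - p_event) / t_mean

Radiation-attributable late effects enter as excess hazards on top of small
non-RT baselines, as step functions of time since diagnosis (a latency
period followed by a constant excess rate). Background (non-PLGG) mortality
is Gompertz in attained age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .cohort import AE_CLASSES, LETHAL_AE_CLASSES


def calibrate_constant_hazard(p_event: float, t_mean: float) -> float:
    """Exponential rate hitting cumulative probability ``p_event`` at ``t_mean``.

    Round-trips with :func:`plggsim.engine.hazard_to_prob` to 1e-12.
    """
    if not 0.0 < p_event < 1.0:
        raise ValueError(f"p_event must be in (0, 1), got {p_event}")
    if t_mean <= 0.0:
        raise ValueError(f"t_mean must be positive, got {t_mean}")
    return -math.log1p(-p_event) / t_mean


@dataclass(frozen=True)
class CalibrationTargets:
    """Published event proportions at mean follow-up, by fusion stratum.

    Defaults are the institutional PLGG cohort summaries (n=363; 130 fused):
    progression 26.92% / 33.48% at mean follow-up 4.7 / 5.6 years and death
    2.31% / 6.87% at 7.7 / 9.6 years for fused / non-fused patients.
    """

    p_progressed_fused: float = 0.2692
    p_progressed_nonfused: float = 0.3348
    p_died_fused: float = 0.0231
    p_died_nonfused: float = 0.0687
    t_progression_fused: float = 4.7
    t_progression_nonfused: float = 5.6
    t_mortality_fused: float = 7.7
    t_mortality_nonfused: float = 9.6

    def __post_init__(self) -> None:
        for name in (
            "p_progressed_fused",
            "p_progressed_nonfused",
            "p_died_fused",
            "p_died_nonfused",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in (
            "t_progression_fused",
            "t_progression_nonfused",
            "t_mortality_fused",
            "t_mortality_nonfused",
        ):
            v = getattr(self, name)
            if v <= 0.0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class GompertzMortality:
    """Background all-cause mortality: rate(age) = rate_at_zero * exp(slope*age).

    Defaults give a smooth, increasing schedule with modal age at death in
    the ninth decade; overridable by an age-indexed table via ``table``.
    """

    rate_at_zero: float = 3.5e-5
    log_slope: float = 0.085
    table: tuple[tuple[float, float], ...] | None = None  # (age, rate) knots

    def __post_init__(self) -> None:
        if self.rate_at_zero < 0 or self.log_slope < 0:
            raise ValueError("Gompertz parameters must be non-negative")
        if self.table is not None:
            ages = [a for a, _ in self.table]
            if ages != sorted(ages) or any(r < 0 for _, r in self.table):
                raise ValueError("mortality table must be age-sorted with rates >= 0")

    def rate(self, age: float) -> float:
        if self.table is not None:
            # step function: last knot at or below the attained age
            r = self.table[0][1]
            for a, ra in self.table:
                if age >= a:
                    r = ra
                else:
                    break
            return r
        return self.rate_at_zero * math.exp(self.log_slope * age)

    def rate_array(self, ages):
        """Vectorized :meth:`rate` over a numpy array of attained ages."""
        ages = np.asarray(ages, dtype=float)
        if self.table is not None:
            knots = np.array([a for a, _ in self.table])
            rates = np.array([r for _, r in self.table])
            idx = np.clip(np.searchsorted(knots, ages, side="right") - 1, 0, len(rates) - 1)
            return rates[idx]
        return self.rate_at_zero * np.exp(self.log_slope * ages)


@dataclass(frozen=True)
class AEHazard:
    """One adverse-event class: non-RT baseline plus RT-attributable excess.

    Both pieces are step functions of time since diagnosis (zero during the
    latency, constant after). The excess applies only to irradiated patients
    and is scaled by the scenario's AE multiplier.
    """

    baseline_rate: float
    excess_rate: float
    baseline_latency: float = 0.0
    excess_latency: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.excess_rate < 0:
            raise ValueError("adverse-event hazards must be non-negative")
        if self.baseline_latency < 0 or self.excess_latency < 0:
            raise ValueError("latencies must be non-negative")

    def rate(self, t: float, rt_received: bool, multiplier: float = 1.0) -> float:
        r = self.baseline_rate if t >= self.baseline_latency else 0.0
        if rt_received and t >= self.excess_latency:
            r += multiplier * self.excess_rate
        return r


#: Synthetic per-class late-effect hazards (per year). Excess rates are
#: order-of-magnitude consistent with survivorship cumulative-incidence
#: curves for irradiated childhood-cancer survivors; baselines are small
#: non-RT rates so the comparison without RT is not degenerate.
DEFAULT_AE_HAZARDS: Mapping[str, AEHazard] = {
    "neurological": AEHazard(baseline_rate=0.0012, excess_rate=0.008, excess_latency=0.0),
    "auditory": AEHazard(baseline_rate=0.0008, excess_rate=0.005, excess_latency=0.0),
    "visual": AEHazard(baseline_rate=0.0006, excess_rate=0.004, excess_latency=0.0),
    "stroke": AEHazard(baseline_rate=0.0005, excess_rate=0.004, excess_latency=5.0),
    "cardiovascular": AEHazard(baseline_rate=0.0006, excess_rate=0.003, excess_latency=5.0),
    "secondary_neoplasm": AEHazard(baseline_rate=0.0004, excess_rate=0.004, excess_latency=5.0),
}

#: Excess mortality (per year) while the flag is active, lethal classes only.
DEFAULT_AE_MORTALITY: Mapping[str, float] = {
    "stroke": 0.03,
    "cardiovascular": 0.02,
    "secondary_neoplasm": 0.05,
}


@dataclass(frozen=True)
class HazardModel:
    """All per-event hazard functions driving the microsimulation.

    Scenario transformations (RT progression benefit, AE-risk scaling) act
    through ``rt_progression_hr`` and ``ae_excess_multiplier``; a freshly
    built model carries the identity values 1.0.
    """

    progression_rate: Mapping[str, float]  # fusion -> pre-progression rate
    plgg_death_rate: Mapping[str, float]  # fusion -> pre-progression rate
    reprogression_hr: float
    post_progression_death_hr: float
    background: GompertzMortality
    ae: Mapping[str, AEHazard]
    ae_mortality: Mapping[str, float]
    rt_progression_hr: float = 1.0
    ae_excess_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.reprogression_hr < 0:
            raise ValueError("reprogression_hr must be >= 0")
        if self.post_progression_death_hr < 1.0:
            raise ValueError(
                "post-progression death hazard must be >= pre-progression "
                f"(hazard ratio >= 1), got {self.post_progression_death_hr}"
            )
        if self.rt_progression_hr <= 0:
            raise ValueError("rt_progression_hr must be positive")
        if not 0.0 <= self.ae_excess_multiplier <= 1.0:
            raise ValueError("ae_excess_multiplier must be in [0, 1]")
        if set(self.ae) != set(AE_CLASSES):
            raise ValueError("ae hazards must cover exactly the six AE classes")
        if set(self.ae_mortality) != set(LETHAL_AE_CLASSES):
            raise ValueError("ae_mortality must cover exactly the lethal AE classes")
        for m in self.ae_mortality.values():
            if m < 0:
                raise ValueError("ae mortality rates must be >= 0")

    # -- spec surface -----------------------------------------------------
    def progression_hazard(self, fusion: str, n_progressions: int, rt_received: bool) -> float:
        r = self.progression_rate[fusion]
        if n_progressions >= 1:
            r *= self.reprogression_hr
        if rt_received:
            r *= self.rt_progression_hr
        return r

    def plgg_death_hazard(self, fusion: str, n_progressions: int) -> float:
        r = self.plgg_death_rate[fusion]
        if n_progressions >= 1:
            r *= self.post_progression_death_hr
        return r

    def background_mortality(self, age: float) -> float:
        return self.background.rate(age)

    def ae_hazard(
        self,
        ae_class: str,
        time_since_dx: float,
        rt_received: bool,
        ae_multiplier: float | None = None,
    ) -> float:
        m = self.ae_excess_multiplier if ae_multiplier is None else ae_multiplier
        return self.ae[ae_class].rate(time_since_dx, rt_received, m)

    def ae_mortality_rate(self, ae_class: str) -> float:
        return self.ae_mortality[ae_class]


def build_hazard_model(
    targets: CalibrationTargets | None = None,
    ae_params: Mapping[str, AEHazard] | None = None,
    background: GompertzMortality | None = None,
    *,
    reprogression_hr: float = 1.5,
    post_progression_death_hr: float = 3.0,
) -> HazardModel:
    """Calibrate the full hazard model from cohort summary targets.

    Progression and PLGG-death rates per fusion stratum come from
    :func:`calibrate_constant_hazard` applied to the published proportions at
    mean follow-up. Having progressed multiplies the progression rate by
    ``reprogression_hr`` and the PLGG death rate by
    ``post_progression_death_hr`` (>= 1 enforced).
    """
    targets = targets if targets is not None else CalibrationTargets()
    ae = dict(ae_params) if ae_params is not None else dict(DEFAULT_AE_HAZARDS)
    return HazardModel(
        progression_rate={
            "fused": calibrate_constant_hazard(
                targets.p_progressed_fused, targets.t_progression_fused
            ),
            "non_fused": calibrate_constant_hazard(
                targets.p_progressed_nonfused, targets.t_progression_nonfused
            ),
        },
        plgg_death_rate={
            "fused": calibrate_constant_hazard(targets.p_died_fused, targets.t_mortality_fused),
            "non_fused": calibrate_constant_hazard(
                targets.p_died_nonfused, targets.t_mortality_nonfused
            ),
        },
        reprogression_hr=reprogression_hr,
        post_progression_death_hr=post_progression_death_hr,
        background=background if background is not None else GompertzMortality(),
        ae=ae,
        ae_mortality=dict(DEFAULT_AE_MORTALITY),
    )


def scale_hazards(model: HazardModel, **multipliers: float) -> HazardModel:
    """Multiplicative perturbation of hazard blocks (used by the PSA).

    Recognized keys: ``progression``, ``plgg_death``, ``ae_excess``,
    ``ae_baseline``, ``background``. Missing keys default to 1.
    """
    for k in multipliers:
        if k not in ("progression", "plgg_death", "ae_excess", "ae_baseline", "background"):
            raise ValueError(f"unknown hazard block {k!r}")
        if multipliers[k] < 0:
            raise ValueError("hazard multipliers must be >= 0")
    mp = multipliers.get("progression", 1.0)
    md = multipliers.get("plgg_death", 1.0)
    me = multipliers.get("ae_excess", 1.0)
    mb = multipliers.get("ae_baseline", 1.0)
    mg = multipliers.get("background", 1.0)
    return replace(
        model,
        progression_rate={k: v * mp for k, v in model.progression_rate.items()},
        plgg_death_rate={k: v * md for k, v in model.plgg_death_rate.items()},
        ae={
            k: replace(v, baseline_rate=v.baseline_rate * mb, excess_rate=v.excess_rate * me)
            for k, v in model.ae.items()
        },
        background=replace(
            model.background,
            rate_at_zero=model.background.rate_at_zero * mg,
            table=None
            if model.background.table is None
            else tuple((a, r * mg) for a, r in model.background.table),
        ),
    )
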