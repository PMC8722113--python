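"""The decision tree: strategy arms, the molecular test, and RT eligibility.

Two strategies are compared. In the *testing* arm every patient's tumor is
assayed at diagnosis and the assay perfectly reveals BRAF-KIAA1549 fusion
status; radiation at first progression is then restricted to non-fused,
RT-eligible patients. In the *no_testing* arm fusion status stays unknown
and every RT-eligible first progressor is irradiated.

RT eligibility mirrors trial entry criteria: age 3-21 years at first
progression, unresectable disease with measurable disease, and — for
children under 10 — at least one prior chemotherapy course.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .cohort import PatientRecord
from .hazards import HazardModel

ARMS = ("testing", "no_testing")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: strategy arm plus model switches."""

    arm: str = "testing"
    rt_benefit: bool = False
    rt_progression_hazard_ratio: float = 0.5
    ae_multiplier: float = 1.0
    discount_rate: float = 0.015
    cycle_length: float = 1.0
    age_cap: float = 100.0
    n_patients: int = 100_000
    n_psa_runs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.rt_progression_hazard_ratio <= 0:
            raise ValueError("rt_progression_hazard_ratio must be positive")
        if not 0.0 <= self.ae_multiplier <= 1.0:
            raise ValueError(f"ae_multiplier must be in [0, 1], got {self.ae_multiplier}")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.age_cap <= 0:
            raise ValueError("age_cap must be positive")

    @property
    def effective_rt_hr(self) -> float:
        """Hazard ratio on progression after RT; 1 when the benefit is off."""
        return self.rt_progression_hazard_ratio if self.rt_benefit else 1.0


def molecular_test(patient: PatientRecord, arm: str) -> str:
    """Run (or skip) the diagnostic assay once at diagnosis.

    The assay is modeled as perfect: in the testing arm it returns the true
    fusion status; the control arm learns nothing. Re-testing is rejected.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    if patient.fusion_knowledge is not None:
        raise ValueError(f"patient {patient.id} was already tested")
    if arm == "testing":
        knowledge = "known_fused" if patient.fusion == "fused" else "known_non_fused"
    else:
        knowledge = "unknown"
    patient.fusion_knowledge = knowledge
    return knowledge


def rt_eligible(patient: PatientRecord) -> bool:
    """RT eligibility, evaluated at the moment of a progression event.

    True iff the patient is 3-21 years old, unresectable with measurable
    disease, at their *first* progression, and either at least 10 years old
    or previously chemotherapy-treated.
    """
    age = patient.age
    return (
        3.0 <= age <= 21.0
        and patient.unresectable
        and patient.measurable_disease
        and patient.n_progressions == 1
        and (age >= 10.0 or patient.chemo_courses >= 1)
    )


def treatment_decision(patient: PatientRecord, knowledge: str, eligible: bool) -> str:
    """Radiate or treat with chemotherapy at first progression.

    Testing arm: RT only for eligible patients known non-fused. Control arm:
    RT for every eligible patient. Everyone else receives chemotherapy.
    """
    if knowledge not in ("known_fused", "known_non_fused", "unknown"):
        raise ValueError(f"unknown fusion knowledge {knowledge!r}")
    if not eligible:
        return "give_chemo"
    if knowledge == "known_fused":
        return "give_chemo"
    return "give_rt"  # known_non_fused, or unknown (control arm)


def apply_scenario(hazards: HazardModel, scenario: ScenarioConfig) -> HazardModel:
    """Stamp the scenario's RT effect and AE-risk scaling onto the hazards.

    With the benefit on, progression hazard after RT is multiplied by the
    configured hazard ratio; the RT-attributable AE excess is scaled by the
    AE multiplier. Hazards of never-irradiated patients are untouched.
    """
    return replace(
        hazards,
        rt_progression_hr=scenario.effective_rt_hr,
        ae_excess_multiplier=scenario.ae_multiplier,
    )
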