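import numpy as np
import pytest
from hypothesis import settings

from plggsim import (
    CohortParams,
    GompertzMortality,
    HazardModel,
    ModelInputs,
    PatientRecord,
    generate_cohort,
)
from plggsim.hazards import AEHazard, DEFAULT_AE_MORTALITY
from plggsim.cohort import AE_CLASSES

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def inputs() -> ModelInputs:
    return ModelInputs.default()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortParams(n_patients=500, seed=123))


@pytest.fixture
def patient() -> PatientRecord:
    return PatientRecord(
        id=0,
        age_at_dx=8.0,
        sex="female",
        fusion="non_fused",
        unresectable=True,
        measurable_disease=True,
        chemo_courses=1,
    )


def make_hazards(
    progression=0.07,
    plgg_death=0.006,
    background=GompertzMortality(),
    ae=None,
    ae_mortality=None,
    **kw,
) -> HazardModel:
    """Hand-assembled hazard model for targeted tests."""
    if ae is None:
        ae = {c: AEHazard(baseline_rate=0.001, excess_rate=0.004) for c in AE_CLASSES}
    return HazardModel(
        progression_rate={"fused": progression, "non_fused": progression},
        plgg_death_rate={"fused": plgg_death, "non_fused": plgg_death},
        reprogression_hr=kw.pop("reprogression_hr", 1.5),
        post_progression_death_hr=kw.pop("post_progression_death_hr", 3.0),
        background=background,
        ae=ae,
        ae_mortality=dict(ae_mortality if ae_mortality is not None else DEFAULT_AE_MORTALITY),
        **kw,
    )


def zero_hazards() -> HazardModel:
    return make_hazards(
        progression=0.0,
        plgg_death=0.0,
        background=GompertzMortality(0.0, 0.0),
        ae={c: AEHazard(0.0, 0.0) for c in AE_CLASSES},
        ae_mortality={c: 0.0 for c in ("stroke", "cardiovascular", "secondary_neoplasm")},
        post_progression_death_hr=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
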