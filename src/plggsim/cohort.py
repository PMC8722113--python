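"""Synthetic diagnosis cohorts for pediatric low-grade glioma (PLGG).

Real institutional patient data behind this analysis are not public, so the
cohort generator emulates their published summary structure: a pediatric
cohort diagnosed between 0.2 and 18.5 years of age (mean 9.8), roughly 36%
carrying the BRAF-KIAA1549 fusion, roughly half female, with trial-entry
attributes (unresectable disease, measurable disease, first-line
chemotherapy) drawn once at diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

AE_CLASSES = (
    "neurological",
    "auditory",
    "visual",
    "stroke",
    "cardiovascular",
    "secondary_neoplasm",
)
#: AE classes that carry excess mortality while active.
LETHAL_AE_CLASSES = ("stroke", "cardiovascular", "secondary_neoplasm")

STATE_LABELS = (
    "pre_progression",
    "first_progression",
    "later_progression",
    "ae_neurological",
    "ae_auditory",
    "ae_visual",
    "ae_stroke",
    "ae_cardiovascular",
    "ae_secondary_neoplasm",
    "dead",
)


@dataclass(frozen=True)
class AgeDistribution:
    """Age-at-diagnosis distribution: a Beta rescaled to [min, max].

    The Beta mean is matched to ``mean_years``; the one remaining shape
    degree of freedom is fixed by ``concentration`` (alpha + beta), which
    controls spread around the mean.
    """

    min_years: float = 0.2
    max_years: float = 18.5
    mean_years: float = 9.8
    concentration: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.min_years < self.mean_years < self.max_years <= 21):
            raise ValueError(
                "age bounds must satisfy 0 < min < mean < max <= 21, got "
                f"min={self.min_years}, mean={self.mean_years}, max={self.max_years}"
            )
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        span = self.max_years - self.min_years
        m = (self.mean_years - self.min_years) / span
        a = m * self.concentration
        b = (1.0 - m) * self.concentration
        return self.min_years + span * rng.beta(a, b, size=n)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the simulated diagnosis cohort."""

    n_patients: int = 100_000
    fusion_prevalence: float = 0.3581
    female_fraction: float = 0.4958
    age_dx: AgeDistribution = field(default_factory=AgeDistribution)
    chemo_first_line_probability: float = 0.7
    unresectable_probability: float = 0.6
    measurable_disease_probability: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        for name in (
            "fusion_prevalence",
            "female_fraction",
            "chemo_first_line_probability",
            "unresectable_probability",
            "measurable_disease_probability",
        ):
            _check_prob(name, getattr(self, name))


@dataclass
class PatientRecord:
    """One simulated individual at a point in (simulated) time."""

    id: int
    age_at_dx: float
    sex: str  # "female" | "male"
    fusion: str  # "fused" | "non_fused"
    unresectable: bool
    measurable_disease: bool
    chemo_courses: int = 0
    alive: bool = True
    current_state: str = "pre_progression"
    time_since_dx: float = 0.0
    n_progressions: int = 0
    rt_received: bool = False
    ae_flags: set = field(default_factory=set)
    fusion_knowledge: str | None = None  # set once by the molecular test

    @property
    def age(self) -> float:
        return self.age_at_dx + self.time_since_dx

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.fusion not in ("fused", "non_fused"):
            raise ValueError(f"fusion must be 'fused' or 'non_fused', got {self.fusion!r}")
        if self.n_progressions < 0:
            raise ValueError("n_progressions must be >= 0")
        if self.rt_received and self.n_progressions < 1:
            raise ValueError("rt_received implies at least one progression")
        bad = set(self.ae_flags) - set(AE_CLASSES)
        if bad:
            raise ValueError(f"unknown adverse-event classes: {sorted(bad)}")


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Draw a fresh diagnosis cohort.

    Every patient starts pre-progression, alive, at ``time_since_dx`` 0 with
    no adverse events. Deterministic given ``params.seed``.
    """
    n = params.n_patients
    if n == 0:
        return []
    rng = np.random.default_rng(params.seed)
    ages = params.age_dx.sample(n, rng)
    female = rng.random(n) < params.female_fraction
    fused = rng.random(n) < params.fusion_prevalence
    unres = rng.random(n) < params.unresectable_probability
    meas = rng.random(n) < params.measurable_disease_probability
    chemo = rng.random(n) < params.chemo_first_line_probability
    return [
        PatientRecord(
            id=i,
            age_at_dx=float(ages[i]),
            sex="female" if female[i] else "male",
            fusion="fused" if fused[i] else "non_fused",
            unresectable=bool(unres[i]),
            measurable_disease=bool(meas[i]),
            chemo_courses=int(chemo[i]),
        )
        for i in range(n)
    ]


def _pct(count: int, denom: int) -> float:
    """Percentage to two decimals, the convention of the cohort table."""
    if denom == 0:
        return float("nan")
    return round(100.0 * count / denom, 2)


def summarize_cohort(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Cohort characteristics table, overall and by fusion status.

    Rows are counts and percentages (two decimals); stratified percentages
    use the stratum count as denominator. Raises on an empty cohort.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    frame = pd.DataFrame(
        {
            "fused": [p.fusion == "fused" for p in cohort],
            "female": [p.sex == "female" for p in cohort],
            "age": [p.age_at_dx for p in cohort],
            "died": [not p.alive for p in cohort],
            "progressed": [p.n_progressions > 0 for p in cohort],
        }
    )

    def column(sub: pd.DataFrame, total: int) -> dict[str, float]:
        n = len(sub)
        return {
            "n": n,
            "pct_of_total": _pct(n, total),
            "age_mean": round(float(sub["age"].mean()), 1) if n else float("nan"),
            "age_min": round(float(sub["age"].min()), 1) if n else float("nan"),
            "age_max": round(float(sub["age"].max()), 1) if n else float("nan"),
            "pct_fused": _pct(int(sub["fused"].sum()), n),
            "pct_female": _pct(int(sub["female"].sum()), n),
            "n_died": int(sub["died"].sum()),
            "pct_died": _pct(int(sub["died"].sum()), n),
            "n_progressed": int(sub["progressed"].sum()),
            "pct_progressed": _pct(int(sub["progressed"].sum()), n),
        }

    total = len(frame)
    out = pd.DataFrame(
        {
            "all": column(frame, total),
            "fused": column(frame[frame["fused"]], total),
            "non_fused": column(frame[~frame["fused"]], total),
        }
    )
    return out


#: Fixed, documented column order of the cohort CSV.
COHORT_CSV_COLUMNS = (
    "id",
    "age_at_dx",
    "sex",
    "fusion",
    "unresectable",
    "measurable_disease",
    "chemo_courses",
)


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """One row per patient, fixed column order (see COHORT_CSV_COLUMNS)."""
    return pd.DataFrame(
        [{c: getattr(p, c) for c in COHORT_CSV_COLUMNS} for p in cohort],
        columns=list(COHORT_CSV_COLUMNS),
    )


def replicate_profile(profile: PatientRecord, n: int) -> list[PatientRecord]:
    """n fresh copies of a representative patient profile (ids 0..n-1)."""
    return [replace(profile, id=i, ae_flags=set(profile.ae_flags)) for i in range(n)]
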