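"""Cost and utility tables (SYNTHETIC defaults, 2018 CAD).

The institutional cost and utility inputs behind the published analysis are
not public. The defaults below are synthetic, order-of-magnitude-plausible
values for a Canadian public payer, surfaced in full in the default config
file and overridable there; nothing is hard-coded elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .cohort import AE_CLASSES

DISEASE_STAGES = ("pre_progression", "first_progression", "later_progression", "dead")


@dataclass(frozen=True)
class CostTable:
    """Per-event and per-year costs in CAD of ``price_year``."""

    surgery_cost: float = 25_000.0
    chemo_course_cost: float = 18_000.0
    rt_course_cost: float = 28_000.0
    molecular_test_cost: float = 400.0
    ae_annual_cost: Mapping[str, float] = field(
        default_factory=lambda: {
            "neurological": 5_000.0,
            "auditory": 1_500.0,
            "visual": 1_500.0,
            "stroke": 8_000.0,
            "cardiovascular": 6_000.0,
            "secondary_neoplasm": 12_000.0,
        }
    )
    ae_acute_cost: Mapping[str, float] = field(
        default_factory=lambda: {
            "neurological": 5_000.0,
            "auditory": 3_000.0,
            "visual": 3_000.0,
            "stroke": 25_000.0,
            "cardiovascular": 15_000.0,
            "secondary_neoplasm": 40_000.0,
        }
    )
    background_annual_cost: float = 3_000.0
    price_year: int = 2018

    def __post_init__(self) -> None:
        for name in (
            "surgery_cost",
            "chemo_course_cost",
            "rt_course_cost",
            "molecular_test_cost",
            "background_annual_cost",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for m_name in ("ae_annual_cost", "ae_acute_cost"):
            m = getattr(self, m_name)
            if set(m) != set(AE_CLASSES):
                raise ValueError(f"{m_name} must cover exactly the six AE classes")
            for k, v in m.items():
                if v < 0:
                    raise ValueError(f"{m_name}[{k!r}] must be >= 0")


@dataclass(frozen=True)
class UtilityTable:
    """Stage utilities and adverse-event multipliers, combined multiplicatively."""

    baseline_utility: Mapping[str, float] = field(
        default_factory=lambda: {
            "pre_progression": 0.92,
            "first_progression": 0.85,
            "later_progression": 0.80,
            "dead": 0.0,
        }
    )
    ae_utility_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {
            "neurological": 0.85,
            "auditory": 0.93,
            "visual": 0.91,
            "stroke": 0.75,
            "cardiovascular": 0.85,
            "secondary_neoplasm": 0.70,
        }
    )

    def __post_init__(self) -> None:
        if set(self.baseline_utility) != set(DISEASE_STAGES):
            raise ValueError("baseline_utility must cover exactly the disease stages")
        for k, v in self.baseline_utility.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"baseline_utility[{k!r}] must be in [0, 1], got {v}")
        if self.baseline_utility["dead"] != 0.0:
            raise ValueError("utility of the dead state must be 0")
        if set(self.ae_utility_multiplier) != set(AE_CLASSES):
            raise ValueError("ae_utility_multiplier must cover exactly the six AE classes")
        for k, v in self.ae_utility_multiplier.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"ae_utility_multiplier[{k!r}] must be in [0, 1], got {v}")


def default_cost_utility_tables(
    seed: int | None = None,
    overrides: Mapping[str, object] | None = None,
) -> tuple[CostTable, UtilityTable]:
    """The documented synthetic default tables, with optional overrides.

    ``overrides`` is a flat mapping of field name to value; mapping-valued
    fields (``ae_annual_cost`` etc.) are merged key-wise. Values violating
    the type invariants are rejected. ``seed`` is accepted for interface
    symmetry; the defaults themselves are deterministic constants
    (uncertainty draws live in :mod:`plggsim.uncertainty`).
    """
    costs = CostTable()
    utils = UtilityTable()
    if overrides:
        cost_fields = {f for f in CostTable.__dataclass_fields__}
        util_fields = {f for f in UtilityTable.__dataclass_fields__}
        cost_kw: dict[str, object] = {}
        util_kw: dict[str, object] = {}
        for key, value in overrides.items():
            if key in cost_fields:
                current = getattr(costs, key)
                if isinstance(current, Mapping):
                    value = {**current, **value}  # type: ignore[dict-item]
                cost_kw[key] = value
            elif key in util_fields:
                current = getattr(utils, key)
                if isinstance(current, Mapping):
                    value = {**current, **value}  # type: ignore[dict-item]
                util_kw[key] = value
            else:
                raise ValueError(f"unknown cost/utility override {key!r}")
        costs = replace(costs, **cost_kw)  # re-runs invariant checks
        utils = replace(utils, **util_kw)
    return costs, utils
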