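"""Configuration handling and experiment orchestration.

A structured YAML config defines the cohort, calibration targets, scenario
switches, cost/utility overrides, uncertainty spreads and the scenario
sweep grid. :func:`validate_config` turns config text into a fully resolved
:class:`ExperimentSpec` (or a structured error report);
:func:`run_experiment` executes the grid and writes CSV outputs plus a
manifest enabling bit-exact re-runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import ModelInputs, run_comparison
from .cohort import AgeDistribution, CohortParams, cohort_to_frame, generate_cohort, summarize_cohort
from .hazards import CalibrationTargets, GompertzMortality, build_hazard_model
from .outcomes import comparison_table, cumulative_incidence
from .strategies import ScenarioConfig
from .tables import default_cost_utility_tables
from .uncertainty import UncertaintySpec, run_psa


class ConfigError(ValueError):
    """Raised with the full list of config violations (never a partial spec)."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


DEFAULT_SWEEP_AE = [round(0.1 * i, 1) for i in range(11)]


@dataclass
class ExperimentSpec:
    """A fully resolved experiment: inputs, scenario grid and seeds."""

    seed: int = 0
    n_patients: int = 100_000
    n_psa_runs: int = 1000
    cohort: CohortParams = field(default_factory=CohortParams)
    targets: CalibrationTargets = field(default_factory=CalibrationTargets)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    inputs: ModelInputs = field(default_factory=ModelInputs.default)
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)
    sweep_rt_benefit: list[bool] = field(default_factory=lambda: [False, True])
    sweep_ae_multiplier: list[float] = field(default_factory=lambda: list(DEFAULT_SWEEP_AE))
    resolved: dict = field(default_factory=dict)  # config echo


_SECTION_KEYS = {
    "seed",
    "n_patients",
    "n_psa_runs",
    "cohort",
    "calibration",
    "scenario",
    "background_mortality",
    "hazard_structure",
    "costs",
    "utilities",
    "uncertainty",
    "sweep",
}


def _build(section: str, errors: list[str], ctor, **kwargs):
    try:
        return ctor(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def validate_config(raw_text: str) -> ExperimentSpec:
    """Parse and validate config text; every violation is reported with its
    key path. Missing keys take the documented defaults (discount rate
    0.015, cohort 100,000, 1000 PSA runs)."""
    errors: list[str] = []
    try:
        cfg = yaml.safe_load(raw_text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"not valid YAML: {exc}"]) from exc
    if not isinstance(cfg, dict):
        raise ConfigError(["top level must be a mapping"])
    for key in cfg:
        if key not in _SECTION_KEYS:
            errors.append(f"{key}: unknown configuration key")

    seed = cfg.get("seed", 0)
    n_patients = cfg.get("n_patients", 100_000)
    n_psa_runs = cfg.get("n_psa_runs", 1000)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
    if not isinstance(n_patients, int) or n_patients <= 0:
        errors.append("n_patients: must be a positive integer")
    if not isinstance(n_psa_runs, int) or n_psa_runs < 0:
        errors.append("n_psa_runs: must be a non-negative integer")

    cohort_cfg = dict(cfg.get("cohort", {}))
    age_cfg = cohort_cfg.pop("age_dx", None)
    age = (
        _build("cohort.age_dx", errors, AgeDistribution, **age_cfg)
        if isinstance(age_cfg, dict)
        else AgeDistribution()
    )
    cohort = _build(
        "cohort",
        errors,
        CohortParams,
        n_patients=n_patients if isinstance(n_patients, int) and n_patients > 0 else 1,
        seed=seed if isinstance(seed, int) else 0,
        age_dx=age or AgeDistribution(),
        **cohort_cfg,
    )
    targets = _build("calibration", errors, CalibrationTargets, **cfg.get("calibration", {}))
    scenario = _build("scenario", errors, ScenarioConfig, **cfg.get("scenario", {}))
    background = _build(
        "background_mortality", errors, GompertzMortality, **cfg.get("background_mortality", {})
    )
    uncertainty = _build("uncertainty", errors, UncertaintySpec, **cfg.get("uncertainty", {}))

    overrides = {**cfg.get("costs", {}), **cfg.get("utilities", {})}
    tables = _build("costs/utilities", errors, default_cost_utility_tables, overrides=overrides)

    structure = cfg.get("hazard_structure", {})
    hazards = None
    if targets is not None and background is not None:
        hazards = _build(
            "hazard_structure",
            errors,
            build_hazard_model,
            targets=targets,
            background=background,
            reprogression_hr=structure.get("reprogression_hr", 1.5),
            post_progression_death_hr=structure.get("post_progression_death_hr", 3.0),
        )

    sweep = cfg.get("sweep", {})
    sweep_rt = sweep.get("rt_benefit", [False, True])
    sweep_ae = sweep.get("ae_multiplier", list(DEFAULT_SWEEP_AE))
    if not isinstance(sweep_rt, list) or not sweep_rt or not all(
        isinstance(b, bool) for b in sweep_rt
    ):
        errors.append("sweep.rt_benefit: must be a non-empty list of booleans")
    if not isinstance(sweep_ae, list) or not sweep_ae:
        errors.append("sweep.ae_multiplier: must be a non-empty list")
    else:
        for m in sweep_ae:
            if not isinstance(m, (int, float)) or not 0.0 <= m <= 1.0:
                errors.append(f"sweep.ae_multiplier: value {m!r} outside [0, 1]")

    if errors:
        raise ConfigError(errors)
    assert cohort and targets and scenario and uncertainty and hazards and tables
    costs, utilities = tables
    resolved = _resolve_echo(cfg, seed, n_patients, n_psa_runs)
    return ExperimentSpec(
        seed=seed,
        n_patients=n_patients,
        n_psa_runs=n_psa_runs,
        cohort=cohort,
        targets=targets,
        scenario=scenario,
        inputs=ModelInputs(hazards=hazards, costs=costs, utilities=utilities),
        uncertainty=uncertainty,
        sweep_rt_benefit=list(sweep_rt),
        sweep_ae_multiplier=[float(m) for m in sweep_ae],
        resolved=resolved,
    )


def _resolve_echo(cfg: dict, seed: int, n_patients: int, n_psa_runs: int) -> dict:
    echo = json.loads(json.dumps(cfg))  # deep copy, YAML-safe types only
    echo.setdefault("seed", seed)
    echo.setdefault("n_patients", n_patients)
    echo.setdefault("n_psa_runs", n_psa_runs)
    return echo


def config_hash(resolved: dict) -> str:
    return hashlib.sha256(
        json.dumps(resolved, sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]


def write_default_config(path: str | Path, seed: int = 0) -> Path:
    """Write the fully surfaced default configuration, commented."""
    costs, utilities = default_cost_utility_tables()
    doc = {
        "seed": seed,
        "n_patients": 100_000,
        "n_psa_runs": 1000,
        "cohort": {
            "fusion_prevalence": 0.3581,
            "female_fraction": 0.4958,
            "chemo_first_line_probability": 0.7,
            "unresectable_probability": 0.6,
            "measurable_disease_probability": 0.9,
            "age_dx": {"min_years": 0.2, "max_years": 18.5, "mean_years": 9.8},
        },
        "calibration": {
            "p_progressed_fused": 0.2692,
            "p_progressed_nonfused": 0.3348,
            "p_died_fused": 0.0231,
            "p_died_nonfused": 0.0687,
            "t_progression_fused": 4.7,
            "t_progression_nonfused": 5.6,
            "t_mortality_fused": 7.7,
            "t_mortality_nonfused": 9.6,
        },
        "scenario": {
            "rt_benefit": False,
            "rt_progression_hazard_ratio": 0.5,
            "ae_multiplier": 1.0,
            "discount_rate": 0.015,
            "cycle_length": 1.0,
            "age_cap": 100.0,
        },
        "costs": {
            "surgery_cost": costs.surgery_cost,
            "chemo_course_cost": costs.chemo_course_cost,
            "rt_course_cost": costs.rt_course_cost,
            "molecular_test_cost": costs.molecular_test_cost,
            "background_annual_cost": costs.background_annual_cost,
            "ae_annual_cost": dict(costs.ae_annual_cost),
            "ae_acute_cost": dict(costs.ae_acute_cost),
            "price_year": costs.price_year,
        },
        "utilities": {
            "baseline_utility": dict(utilities.baseline_utility),
            "ae_utility_multiplier": dict(utilities.ae_utility_multiplier),
        },
        "uncertainty": {"hazard_log_sd": 0.1, "utility_logit_sd": 0.1, "cost_cv": 0.1},
        "sweep": {"rt_benefit": [False, True], "ae_multiplier": DEFAULT_SWEEP_AE},
    }
    header = (
        "# plggsim experiment configuration (fully resolved defaults).\n"
        "# Calibration targets are published institutional cohort summaries.\n"
        "# SYNTHETIC: every value under 'costs' and 'utilities' is a synthetic,\n"
        "# order-of-magnitude-plausible default (2018 CAD) standing in for\n"
        "# unpublished institutional inputs; override freely.\n"
    )
    path = Path(path)
    path.write_text(header + yaml.safe_dump(doc, sort_keys=False))
    return path


def _write_cell(
    out: Path, name: str, spec: ExperimentSpec, scenario: ScenarioConfig, seeds: tuple[int, int]
) -> dict:
    """Run one scenario cell (both arms) and write its CSV outputs."""
    cohort_seed, traj_seed = seeds
    cell_dir = out / name
    cell_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(replace(spec.cohort, n_patients=spec.n_patients, seed=cohort_seed))
    bundle = run_comparison(cohort, spec.inputs, scenario, traj_seed=traj_seed)
    comp = bundle.comparison
    comparison_table(bundle.testing_summary, bundle.no_testing_summary, comp).to_csv(
        cell_dir / "summary.csv"
    )
    horizon = scenario.age_cap - spec.cohort.age_dx.min_years
    curves = []
    for arm_name, arm in (("testing", bundle.testing), ("no_testing", bundle.no_testing)):
        for event in ("death", "stroke", "secondary_neoplasm", "cardiovascular"):
            df = cumulative_incidence(arm, event, horizon=horizon)
            df.insert(0, "event", event)
            df.insert(0, "arm", arm_name)
            curves.append(df)
    pd.concat(curves, ignore_index=True).to_csv(cell_dir / "cumulative_incidence.csv", index=False)
    nnt = comp.nnt_to_change_decision
    record = {
        "cell": name,
        "rt_benefit": scenario.rt_benefit,
        "ae_multiplier": scenario.ae_multiplier,
        "delta_qalys": comp.delta_qalys,
        "delta_cost_total": comp.delta_cost_total,
        "delta_life_years": comp.delta_life_years,
        "decision_change_fraction": comp.decision_change_fraction,
        "nnt_to_change_decision": nnt if nnt is not None else float("nan"),
        "dominance": comp.dominance,
    }
    if spec.n_psa_runs >= 2:
        psa = run_psa(
            replace(spec.cohort, n_patients=spec.n_patients),
            spec.inputs,
            scenario,
            spec.uncertainty,
            n_runs=spec.n_psa_runs,
            master_seed=traj_seed,
        )
        psa.ce_plane().to_csv(cell_dir / "ce_plane.csv", index=False)
        pd.DataFrame(
            [{"field": k, "lo": v[0], "hi": v[1]} for k, v in psa.intervals.items()]
        ).to_csv(cell_dir / "intervals.csv", index=False)
    return record


def run_experiment(spec: ExperimentSpec, out_dir: str | Path, quiet: bool = False) -> Path:
    """Run the scenario grid and write all outputs; returns the manifest path.

    Fails before simulating if the output directory is unwritable. The grid
    is the base scenario pair plus every (rt_benefit, ae_multiplier) cell.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    if not spec.sweep_rt_benefit or not spec.sweep_ae_multiplier:
        raise ValueError("scenario grid must be non-empty")

    cells: list[tuple[str, ScenarioConfig]] = [("base", spec.scenario)]
    for b in spec.sweep_rt_benefit:
        for m in spec.sweep_ae_multiplier:
            name = f"rt_benefit_{'on' if b else 'off'}__ae_{m:.1f}"
            cells.append((name, replace(spec.scenario, rt_benefit=b, ae_multiplier=m)))

    root = np.random.SeedSequence(spec.seed)
    seeds = [
        tuple(int(s) % 2**31 for s in child.generate_state(2)) for child in root.spawn(len(cells))
    ]
    records = []
    for (name, scenario), cell_seeds in zip(cells, seeds):
        if not quiet:
            print(f"running cell {name} (n={spec.n_patients})")
        records.append(_write_cell(out, name, spec, scenario, cell_seeds))
    pd.DataFrame(records).to_csv(out / "grid_results.csv", index=False)

    manifest = {
        "package": "plggsim",
        "version": __version__,
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "n_psa_runs": spec.n_psa_runs,
        "config": spec.resolved,
        "config_hash": config_hash(spec.resolved),
        "cells": [name for name, _ in cells],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def rerun_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Regenerate an experiment bit-exactly from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    spec = validate_config(yaml.safe_dump(manifest["config"]))
    return run_experiment(spec, out_dir, quiet=True)


def write_inputs(spec: ExperimentSpec, out_dir: str | Path) -> None:
    """Write the generated cohort and its characteristics table as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(replace(spec.cohort, n_patients=spec.n_patients, seed=spec.seed))
    cohort_to_frame(cohort).to_csv(out / "cohort.csv", index=False)
    summarize_cohort(cohort).to_csv(out / "cohort_summary.csv")
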