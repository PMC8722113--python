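# plggsim

A cost-utility microsimulation of **molecular testing for the BRAF-KIAA1549
fusion to guide radiation therapy (RT) in pediatric low-grade glioma (PLGG)**.

PLGG is the most common childhood brain tumor. Patients carrying the
BRAF-KIAA1549 fusion progress less and survive longer than fusion-negative
patients, and RT — while it improves progression-free survival — carries
decades-long risks of stroke, secondary neoplasms, cardiovascular disease and
sensory/neurological deficits. A perfect molecular test at diagnosis lets
clinicians withhold RT from fusion-positive patients at first progression.
`plggsim` quantifies what that test is worth: the incremental discounted
life-years, quality-adjusted life-years (QALYs) and costs (2018 CAD) of a
*testing* strategy versus *no testing*, and the number needed to test (NNT)
to change one radiation decision.

The package is aimed at health-economics and outcomes researchers who want a
fully reproducible, configurable implementation of this decision problem —
and at methodologists who want a compact, well-tested example of an
individual-level state-transition model with a deterministic Markov oracle.

## Model

- **Decision tree.** At diagnosis, the testing arm assays fusion status (the
  assay is modeled as perfect); the control arm learns nothing. At *first*
  progression, RT is given to RT-eligible patients — in the testing arm only
  if the patient is known fusion-negative. Eligibility mirrors trial entry
  criteria: age 3–21 years, unresectable disease with measurable disease,
  and ≥ 1 prior chemotherapy course for children under 10.
- **State-transition engine.** Each patient advances in annual cycles from
  diagnosis to death (age cap 100). Disease stage moves pre-progression →
  first progression → later progression(s); six adverse-event (AE) classes
  accumulate as concurrent flags; death (PLGG-related, background, or
  AE-related for stroke / cardiovascular / secondary neoplasm) is absorbing.
  Competing events within a cycle are composed from independent hazards via
  a total-rate draw with the event type chosen proportional to its rate.
- **Calibration.** Disease hazards are constant (exponential) per fusion
  stratum, λ = −ln(1 − p)/t̄, pinned to published cohort summaries (n = 363;
  progression 26.92%/33.48% at mean follow-up 4.7/5.6 y, death 2.31%/6.87%
  at 7.7/9.6 y for fused/non-fused). RT-attributable late effects enter as
  excess hazards with class-specific latencies; background mortality is
  Gompertz in attained age.
- **Payoffs.** QALYs weight each cycle by a stage utility times the product
  of active AE multipliers (multiplicative method); costs split into PLGG
  treatment, AE, and background healthcare expenditure; everything is
  discounted at 1.5%/year. Both arms share one per-patient random stream
  (common random numbers), so arm differences isolate the decision change.
- **Uncertainty.** Probabilistic sensitivity analysis resamples hazards
  (log-normal), utilities (logit-normal) and costs (gamma) and reruns both
  arms per draw, yielding percentile confidence intervals and the
  cost-effectiveness plane.

The institutional cost/utility inputs behind the published analysis are not
public; the defaults here are documented **synthetic** stand-ins, fully
surfaced in the config file. Headline magnitudes are therefore illustrative;
the package's tested claims are structural (calibration exactness, oracle
agreement, dominance direction, monotone response to the AE-risk dial).

## Worked example

```python
import plggsim as pg

cohort = pg.generate_cohort(pg.CohortParams(n_patients=20_000, seed=1))
inputs = pg.ModelInputs.default()
scenario = pg.ScenarioConfig(rt_benefit=False, ae_multiplier=1.0)
bundle = pg.run_comparison(cohort, inputs, scenario, traj_seed=1)

from plggsim.outcomes import comparison_table
print(comparison_table(bundle.testing_summary, bundle.no_testing_summary,
                       bundle.comparison).round(2))
c = bundle.comparison
print(f"\nNNT to change a radiation decision: {c.nnt_to_change_decision:.1f}")
print(f"Dominance: {c.dominance}")
```

prints

```
                 intervention    control    delta
life_years              31.64      31.40     0.24
qalys                   26.51      26.19     0.32
cost_total          193568.08  199101.46 -5533.38
cost_plgg            77235.79   77209.42    26.38
cost_ae              21404.75   27682.78 -6278.04
cost_background      94927.54   94209.26   718.28

NNT to change a radiation decision: 10.9
Dominance: dominant
```

Reading this: with no assumed RT survival benefit, testing 20,000 simulated
patients spares the ~9% of them who are fusion-positive, RT-eligible first
progressors from radiation. That buys 0.32 discounted QALYs per patient and
saves $5,533 per patient — almost entirely avoided adverse-event costs
(`cost_ae` delta) — so the testing strategy is *dominant* (more effective
and cheaper). About 11 patients must be tested to change one radiation
decision.

A CLI covers the same pipeline stage by stage:

```bash
plgg-sim generate-inputs --seed 1 --n-patients 1000 --out out/inputs
plgg-sim simulate --seed 1 --n-patients 20000 --rt-benefit off --out out/base
plgg-sim psa --seed 1 --n-patients 2000 --n-runs 200 --out out/psa
plgg-sim sweep --config out/inputs/config.yaml --out out/sweep   # full grid
plgg-sim report out/sweep
```

Every experiment directory contains a `manifest.json` (seed, resolved
config, version, config hash) from which the numeric outputs can be
regenerated byte-identically.

## Layout

- `src/plggsim/cohort.py` — synthetic diagnosis cohorts and the
  characteristics table
- `src/plggsim/hazards.py` — exponential calibration, AE excess hazards,
  background mortality
- `src/plggsim/tables.py` — synthetic cost/utility tables (2018 CAD)
- `src/plggsim/strategies.py` — decision tree, molecular test, RT
  eligibility, scenario switches
- `src/plggsim/engine.py` — the state-transition engine (per-patient and
  vectorized paths)
- `src/plggsim/markov.py` — deterministic occupancy oracle for the engine
- `src/plggsim/outcomes.py` — payoff accrual, cumulative incidence,
  strategy comparison
- `src/plggsim/uncertainty.py` — probabilistic sensitivity analysis
- `src/plggsim/experiment.py`, `src/plggsim/cli.py` — config validation,
  scenario grids, manifests, CLI

See `docs/methods.md` for modeling assumptions, defaults and limitations.
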