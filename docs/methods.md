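# Methods

This note records the model behind `plggsim`, its assumptions, the defaults
and why they were chosen, and what the synthetic inputs do and do not
establish about real data.

## Decision problem

Two strategies for newly diagnosed pediatric low-grade glioma (PLGG) after
initial surgery are compared over a lifetime horizon:

- **Testing (intervention):** a molecular assay at diagnosis reveals
  BRAF-KIAA1549 fusion status. At first progression, radiation therapy (RT)
  is restricted to RT-eligible patients known to be fusion-negative;
  everyone else receives chemotherapy.
- **No testing (control):** fusion status stays unknown; every RT-eligible
  first progressor is irradiated.

The assay is modeled as perfect (sensitivity = specificity = 1), so the two
arms differ only for fusion-positive, RT-eligible first progressors — the
group whose treatment the test changes. RT eligibility follows trial-style
entry criteria: age 3–21 years at first progression, unresectable disease
with measurable disease, and, for children under 10, at least one prior
chemotherapy course. RT is modeled only at first progression; later
progressions always receive chemotherapy.

## State-transition model

Each patient is simulated in discrete cycles (default 1 year, configurable;
the parameter-recovery test uses 0.1-year cycles) from diagnosis to death or
an age cap of 100 years. The state is a disease stage — pre-progression,
first progression, later progression(s), dead — plus six concurrent
adverse-event (AE) flags: neurological, auditory, visual, stroke,
cardiovascular, secondary neoplasm. The model's reported state labels treat
AE states alongside the progression states (an AE-onset cycle reports the AE
state), but internally AEs are coexisting boolean conditions on top of the
disease stage: a patient can live with both a stroke and a secondary
neoplasm, which is exactly what the multiplicative utility rule presupposes.

**Competing events.** Within a cycle, the active hazards (progression,
PLGG-related death, background death, AE onsets for unflagged classes, AE
death for active lethal flags) compete. The cycle draws "any event" with
probability 1 − exp(−Λ·dt), Λ the total rate, and picks the event type with
probability proportional to its rate — the discrete-cycle analogue of a
Gillespie step. This makes at most one event fire per cycle, with a
well-defined, order-unbiased resolution; the alternative (sequential
Bernoulli draws per event) was rejected because its outcome depends on
event ordering.

**Execution paths.** A per-patient reference loop
(`simulate_trajectory` + `accrue`) and a vectorized cohort engine
(`simulate_cohort`) implement the same arithmetic; a test drives both with
identical uniform streams and requires event-for-event and
payoff-for-payoff agreement. A third, fully deterministic path
(`expected_occupancy_markov`) expands the state space to
stage × RT flag × 2⁶ AE combinations + dead (385 states), builds the
cycle-wise transition matrix from the same event probabilities, and iterates
it; the microsimulation must match its occupancy within binomial sampling
error.

**Common random numbers.** All trajectory randomness comes from a
counter-based (Philox) uniform matrix keyed by one seed: row i is patient
i's stream, column k its cycle-k draw. Re-using the seed across arms and
scenarios couples the patients exactly, so strategy deltas are free of
between-arm Monte-Carlo noise and the null scenario (below) is an identity,
not an approximation.

## Hazards and calibration

- **Disease hazards.** Constant (exponential) rates per fusion stratum,
  calibrated so the cumulative event probability at the published mean
  follow-up reproduces the published event proportion exactly:
  λ = −ln(1 − p)/t̄. Targets (n = 363 institutional cohort): progression
  26.92% at 4.7 y (fused) and 33.48% at 5.6 y (non-fused); death 2.31% at
  7.7 y and 6.87% at 9.6 y. The patient-level estimation behind the original
  analysis is not reproducible without the data; the exponential form is the
  simplest model matching the printed summaries exactly at the calibration
  point.
- **Progression history.** Having progressed multiplies the progression
  rate by `reprogression_hr` (default 1.5) and the PLGG death rate by
  `post_progression_death_hr` (default 3.0, constrained ≥ 1 so
  post-progression mortality can never fall below pre-progression). The
  calibrated stratum rates anchor the pre-progression state. Chemotherapy
  carries cost but no separate efficacy parameter: its effect is part of
  the calibrated baseline hazards.
- **RT effect on progression.** A configurable hazard ratio (default 0.5)
  applied to the progression rate of irradiated patients when the
  `rt_benefit` scenario switch is on; with the switch off the ratio is
  forced to 1. The default is a stand-in for digitized trial
  progression-free-survival curves; no published numeric hazard ratio
  exists, so the value is surfaced in config, never buried.
- **Adverse events.** Each class has a small non-RT baseline rate plus an
  RT-attributable excess, both step functions of time since diagnosis
  (latency, then constant). Vascular/neoplastic classes use a 5-year
  latency. The scenario's `ae_multiplier` ∈ [0, 1] scales only the excess —
  0 is "no increased risk from RT", 1 the full survivorship-study-era risk;
  the scenario sweep walks this dial in 10% steps. Excess magnitudes are
  synthetic but order-of-magnitude consistent with cumulative-incidence
  curves for irradiated childhood-cancer survivors (a few per mille per
  year per class, i.e. 10–25% cumulative per class over 40 years). AE risk
  is independent of the number of progressions and of treatment line.
- **AE mortality.** Stroke, cardiovascular disease and secondary neoplasm
  add excess death rates while flagged (0.03, 0.02, 0.05 per year).
- **Background mortality.** Gompertz in attained age,
  λ(a) = 3.5·10⁻⁵·e^(0.085a) — a smooth, increasing schedule with modal age
  at death in the ninth decade — shared by both fusion strata and
  overridable by an age-indexed rate table. No specific national life table
  is encoded.

## Cohort generation

Age at diagnosis is a Beta distribution rescaled to [0.2, 18.5] years with
mean matched to 9.8 by fixing the concentration (α+β = 4); bounded support
with a single shape constraint is the least structured choice matching the
printed mean and range. Fusion prevalence (35.81%), female fraction
(49.58%), and the trial-entry attributes — unresectable (0.6), measurable
disease (0.9), first-line chemotherapy (0.7) — are independent Bernoulli
draws fixed at diagnosis. The three attribute probabilities are not
published; the defaults were chosen once as plausible for a progressive
PLGG population and yield a decision-change fraction near 9–10% (NNT ≈ 11,
close to the published 9.5). "Unresectable" and "measurable disease" are
static entry criteria, not dynamic disease features.

## Payoffs

- **Discounting:** (1 + r)^(−t) at r = 1.5%/year, applied at cycle start,
  annual compounding. The rate is the published national-guideline value;
  the compounding convention is this package's choice.
- **Half-cycle handling:** payoffs accrue for the full cycle in the state
  occupied at cycle start; the death cycle credits half a cycle of
  life-years, QALYs and recurring costs; nothing accrues after death. No
  other half-cycle correction is applied.
- **Utilities:** stage utilities (0.92 / 0.85 / 0.80 / 0) times the product
  of active AE multipliers (0.70–0.93 per class) — the multiplicative
  method for comorbid conditions. Dead is structurally 0.
- **Costs (2018 CAD, synthetic):** one-time surgery ($25,000, at
  diagnosis), molecular test ($400, testing arm), RT course ($28,000) or
  chemotherapy course ($18,000) at each progression event, acute AE onset
  costs ($3,000–$40,000); recurring per-year AE management costs
  ($1,500–$12,000 per class) and background healthcare expenditure
  unrelated to PLGG ($3,000/year alive). `cost_plgg` collects disease
  treatment plus the test, `cost_ae` the AE costs, `cost_background` the
  rest; the three sum exactly to `cost_total`.

## The null scenario

With `ae_multiplier = 0` and `rt_benefit` off, RT has no modeled effect on
any hazard, so under common random numbers the two arms produce identical
trajectories for every patient. Outcome identity additionally requires the
payoffs attached to the (different) treatment decisions to coincide, so the
package's null configuration (`null_scenario_inputs`) also zeroes the test
cost and sets the RT course cost equal to the chemotherapy course cost.
Under that configuration every per-patient outcome and every delta is
exactly zero — a strong end-to-end check of the coupling.

## Probabilistic sensitivity analysis

Per run, hazards are perturbed by log-normal multipliers (one per block:
progression, PLGG death, AE excess, AE baseline, background), utilities on
the logit scale (boundary values 0 and 1 are structural and stay fixed),
and costs by gamma draws with fixed coefficient of variation — conventional
PSA families; none are published for this problem. The original analysis
bootstrapped utility inputs only; `UncertaintySpec.utility_only()`
reproduces that scope, while the default perturbs all blocks (σ = 0.1,
CV = 0.1). The cohort and its uniform streams are held fixed across runs,
so percentile intervals (default 95%, linear interpolation between order
statistics) reflect parameter uncertainty alone; first-order Monte-Carlo
error is reported separately as the patient-level standard error of the
fixed-input run. Per-run cohort size is independently configurable because
desk-scale work needs 1,000–10,000 patients; the published analysis used
100,000 patients and 1,000 runs.

## Problem sizes used in tests and the acceptance script

The test suite runs the oracle comparison at 10,000 patients × 40 cycles,
parameter recovery at 50,000 patients × 0.1-year cycles, the dominance and
monotonicity checks at 20,000 and 10,000 patients, and PSA mechanics at 50
runs × 2,000 patients. `scripts/acceptance.py` uses 20,000 patients per arm
(100,000 for cohort structure) and a 50-run PSA. These sizes were chosen so
the whole pipeline re-runs from scratch in seconds on one CPU while keeping
Monte-Carlo error far below the effect sizes tested; the vectorized engine
handles the full 100,000-patient configuration in a few seconds per arm if
the published scale is wanted.

## What the synthetic inputs do and do not establish

The generator reproduces the *structure* the analysis assumes: cohort
composition, fusion-stratified event proportions at their mean follow-up
times, RT-conditional excess AE risk, and cost/utility tables with the
right invariants. It does not reproduce the unpublished patient-level
survival curves, the survivorship-study cumulative-incidence curves, or the
institutional cost/utility values. Passing tests therefore establish that
the pipeline is internally correct (calibration exact, engine equals its
deterministic oracle, coupling exact, comparisons well-formed) and that the
qualitative published findings — testing dominant in both radiation-effect
scenarios, benefit growing with AE risk, NNT of order ten — follow from any
inputs with this structure. Headline magnitudes (QALYs, dollar totals) are
properties of the synthetic defaults, not estimates for real patients.

## Known limitations

- Exponential disease hazards imply that, absent death, progression
  eventually occurs with probability 1; the age window on RT eligibility
  (3–21 years) keeps this from inflating the decision-change fraction, but
  late-progression behavior is an extrapolation.
- Targeted therapies, proton therapy, NF1 patients, first-line RT, RT at
  later progressions, and fusion-dependent RT efficacy are out of scope.
- The assay is perfect; imperfect-test branches are not modeled.
- AE history does not alter disease hazards (and vice versa) beyond the
  explicit AE mortality rates.
- Background mortality is a two-parameter Gompertz, not a national life
  table (a rate table can be supplied via config).
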