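# Methods

## Model structure

The engine (`depscreen_cea.engine`) is an annual-cycle cohort model
with two survival states, alive and dead. Living members are well or
depressed; depression status is re-drawn every cycle from the
age-specific 12-month probability, i.e. a prevalence-based, memoryless
model rather than incidence/duration dynamics. This matches the input
data available (12-month prevalences by age group) and keeps every
cycle an expectation over the same one-year decision tree:

1. **Depression assignment.** `d = p_dep(age) − feedback` (see
   *Remission feedback* below; `feedback = 0` in the status-quo arm).
2. **Detection.** Screening arms detect depressed members with the
   joint sensitivity of the cascade; screen-negative depressed members
   fall back to the background community-diagnosis route
   (probability 0.52) within the same cycle — screening supplements
   usual care rather than replacing it. This fallback is a switch
   (`fn_fallback`) because either reading is defensible. Well members
   are falsely detected with one minus the joint specificity. The
   status-quo arm detects depressed members with the community rate and
   produces no false positives.
3. **Treatment entry** with probability 0.61 among the detected, true
   and false positives alike. Whether screen-detected cases should
   bypass this gate is genuinely unclear; the gate applies by default
   and `screen_positive_treatment_gate=False` sends screen-positives
   straight to treatment.
4. **Adequacy** 0.75 (collaborative care) vs 0.44 (usual care);
   **remission** 0.67 among adequately treated depressed members.
   Inadequately treated and untreated depression gains nothing.
5. **Accrual.** Utility: well and false-positive years at 1.0,
   unremitted depressed years at 0.52, the remission year at 0.76
   (afterwards the person is simply re-drawn from prevalence — the
   remission utility applies only in the remission cycle). Costs:
   per-administration screening for every living member of a screening
   arm; annual treatment cost ($2,879 CC / $2,016 UC) per treatment
   entrant; lost productivity ($2,584) per unremitted depressed
   person-year. False positives incur treatment cost but no utility
   change and no productivity cost.
6. **Mortality**, uniform: no depression-specific excess (suicide
   deaths treated as negligible).
7. Cycle *t* is weighted by survival to the start of the cycle and by
   `(1+r)^−t`, `r = 3%/yr`. No half-cycle correction is applied — the
   choice is deliberate and documented so that deviations from
   published cohort totals are attributable.

The well-state utility (1.0) is not part of the published input table;
it follows from the QALY convention and the assumption that healthy
people receiving (unnecessary) treatment experience no utility change.
It is exposed in the config.

### Remission feedback

The intervention arms carry a memory term: the probability of
depression next cycle is reduced by the *population-level incremental
remitted fraction* of the previous cycle,

```
feedback(t+1) = max(0, d(t)·r_arm − p_dep(t)·r_sq)
```

where `r_arm` and `r_sq` are the per-depressed remission rates of the
arm and of the status-quo cascade. The rationale is that early,
adequate treatment reduces relapse, so an arm that remits more people
than the status quo sees fewer prevalent cases the following year. The
exact construction of this feedback is the least-determined part of the
model, so it is a pluggable policy (`feedback_policy`):

* `incremental_remissions` (default) — the population-count reading
  above. With the shipped inputs it reproduces the published
  decomposition of the intervention's incremental cost into its
  treatment-side and productivity-savings components (see
  *Calibration*), which is why it is the default.
* `proportional` — the per-depressed excess remission rate applied
  multiplicatively to next year's probability. This stronger feedback
  produces a larger QALY gain (≈0.45 vs ≈0.39) and near-total
  cancellation of the incremental cost.
* `none` — no memory.

### Screening cost

Screening cost is built bottom-up: 6 nurse-minutes at $34/h plus 1
physician-minute at $83/h for the PHQ-2, plus 3 physician-minutes for
the PHQ-9 applied to the expected PHQ-2-positive fraction
(`d·se₂ + (1−d)·(1−sp₂)`, recomputed each cycle from the arm's current
depressed fraction). PHQ-9-only arms pay the nurse plus 3
physician-minutes for everyone. The registered `c_screening` parameter
(base $5, range $3–$7) rescales this wage-based computation
(multiplier = value/5) so the screening-cost uncertainty band remains
usable in one-way and probabilistic analyses without discarding the
positive-rate adjustment.

The two screening stages are treated as conditionally independent
given true status. Because the PHQ-2 items are a subset of the PHQ-9,
real stages are positively correlated and the series formulas
(`se₂·se₉`, `1−(1−sp₂)(1−sp₉)`) overstate the joint specificity
somewhat; results conditional on the published operating
characteristics are unaffected, but users substituting their own
estimates should supply *joint* characteristics if they have them.

## Synthetic age schedule and calibration

The model needs per-age depression and death probabilities; the
originals come from a national life table and a city health survey
that are not redistributable. `depscreen_cea.synthetic_inputs`
generates stand-ins:

* **Mortality**: discrete-time Gompertz,
  `q(a) = 1 − exp(−L·e^{s(a−20)})`, defaults `L = 3.633e-4`,
  `s = 0.058`/yr.
* **Depression**: step-constant general-population prevalence over age
  bands 20–29/30–39/40–49/50–59/60–70 (defaults 0.0806, 0.0865,
  0.0953, 0.1002, 0.0865), times the primary-care multiplier 1.74.

The two generator scales (Gompertz level; a common prevalence-band
scale) were root-found **once** so that the status-quo arm reproduces
its published discounted totals ($11,867 and 24.19 QALYs); the
resulting values were frozen as the defaults above. Under them,
discounted quality-unadjusted survival from 20 to 70 at 3% is 26.01
years, inside the 25–27 window implied by the published QALY totals,
and the band prevalences average ≈8.9%, a realistic urban
12-month figure. Every downstream quantity — the intervention's
incremental cost ($571), QALY gain (0.385), ICER ($1,481/QALY), and
the one-way ICERs with productivity removed ($8,706) or capped at age
64 ($1,797) — is then a genuine model output, landing within 15% of
the published values ($660, 0.38, $1,726, $8,840, $1,870).

What the synthetic schedule does *not* emulate: the sampling noise of
a real survey (bands are exact), cohort mortality improvement (the
life table is a period table), and any age-by-severity interaction.
Tests passing on the synthetic schedule therefore validate the model
mechanics and the calibrated magnitudes, not the exact published point
estimates; users can substitute real schedules via `read_schedule`.
The synthetic mortality is also lighter than a current US period life
table at older ages — a consequence of matching the published
discounted totals rather than the life table itself.

## Incremental analysis conventions

`incremental_analysis` orders strategies by effectiveness (ties:
cheaper first) and iteratively removes (a) costlier arms at equal
effectiveness and least-effective arms beaten outright by a cheaper,
better arm — labelled `dominated` — and (b) arms whose ICER against
their predecessor exceeds the ICER of the next more effective arm —
labelled `extendedly_dominated` — until frontier ICERs increase
strictly. With this convention an arm that is both more expensive and
less effective than a *later* arm is recorded as extendedly dominated
(a mixture of its neighbours dominates it), matching how
decision-analysis packages print fully incremental tables. Frontier
membership is identical to the convex-hull definition (property-tested
against a brute-force pair/blend oracle). ICERs are displayed to the
nearest dollar, halves away from zero; internals keep full precision
(whence a displayed ratio of printed increments can differ by a few
dollars from the ratio of unrounded internals).

## Sensitivity analyses

**One-way** (`one_way`): one parameter at its low/high bound, all else
at base, reporting ΔC, ΔE and ICER of strategy 4 vs 1. Cut-off
parameters swap in the published (sensitivity, specificity) pair for
the alternative cut-off; the lost-productivity age cap compares
all-ages accrual against capping at 64 (valuing only working-age
output); the depression-probability bound is ±20% via a prevalence
scale factor. Overriding the productivity total rescales its
absenteeism/presenteeism components proportionally so their identity
holds.

**PSA** (`run_psa`): every registered parameter drawn independently
from triangular(low, mode, high) by inverse CDF; probability draws are
clipped to [0,1] as a guard (the shipped bounds already respect it).
Defaults: 10,000 draws, fixed seed (echoed in the output), WTP grid
$0–50,000 in $1,000 steps. The CEAC is the fraction of draws in which
the intervention's net monetary benefit (`wtp·ΔE − ΔC`) is positive;
the EVPI is `E[max_s NMB_s] − max_s E[NMB_s]` over all five arms
(clipped at zero against float roundoff). The 95% plausible interval
is read from order statistics of the draws ranked on the
cost-effectiveness plane — cost-saving draws first, then increasing
ICER, ties broken by NMB at the reference WTP — because ranking purely
by NMB buries cost-saving draws in mid-ranks and cannot express a
"cost-saving" interval end. This is one defensible reading of a
simulation interval for a ratio statistic; exact reproduction of a
published interval additionally depends on the (unreported) draw
count, seed and percentile convention, so only qualitative agreement
is expected.

The default WTP grid stops at $50,000 deliberately: in this model the
PHQ-9-only collaborative-care arm has an ICER of roughly $105,000/QALY
against the two-stage arm, so beyond ~$70,000 the all-strategy EVPI
begins to reflect *that* decision margin and rises again. Within the
decision-relevant grid the EVPI shows the expected peak (near the base
ICER) followed by decay; the grid is a user-settable argument.

Parameters are sampled without correlation, including the four test
operating characteristics — a simplification; the joint-sampling
policy can be replaced by passing a restricted `sampled` list and
overriding parameters externally.

## Microsimulation

`run_microsimulation` is a first-order Monte Carlo mirror of the
cohort engine: each individual draws depression, treatment entry,
remission and death as Bernoulli events with exactly the per-cycle
probabilities of the cohort recursion (including the deterministic
feedback trajectory). Its expectation equals the cohort run — verified
to within three standard errors at n = 20,000 — and it exposes
between-individual variability. The cohort engine is authoritative for
all reported results, since ICERs are ratios of expectations.

## Numerical conventions and degenerate inputs

* Cycle quantities are exact closed-form expectations (validated to
  1e−12 against an exhaustive enumeration of the one-cycle decision
  tree), so there is no within-cycle simulation error.
* Zero-width triangulars return their mode; a zero Gompertz level is
  the no-mortality limit; prevalence × multiplier is clipped to 1 with
  a warning.
* Schedules must cover the age range contiguously with probabilities
  in [0,1] and nondecreasing mortality; violations raise with the
  offending age named.
* Equal-effectiveness ties in the frontier keep the cheaper arm; an
  exact cost-and-effect tie leaves both arms in place.
* All currency is constant 2015 USD; no CPI machinery is included.

## Problem sizes

Default analyses run five strategies × 50 annual cycles; the shipped
PSA uses 10,000 draws (≈10 s on one CPU) and the microsimulation
cross-check 20,000 individuals. These sizes give Monte Carlo error
well below the tolerances used in the test suite.

## Known limitations

* No partial-response utility gain (insufficient published data), no
  comorbidity cost offsets, no suicide mortality, no time or
  transportation costs — all deliberate exclusions inherited from the
  modelled intervention's evaluation design.
* The memoryless prevalence model cannot represent episode duration or
  recurrence structure beyond the one-year feedback term.
* Conditional independence of the two screening stages (see above).
* The synthetic schedule is a calibrated stand-in, not survey or
  life-table data.
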