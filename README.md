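# depscreen-cea

A decision-analytic model of **universal two-stage depression screening
(PHQ-2 followed by PHQ-9) with collaborative care** in adult primary
care, for health-economics analysts evaluating screen-and-treat
programmes. The package implements the full pipeline: an annual-cycle
Markov cohort model over ages 20–70, a fully incremental
cost-effectiveness analysis across five strategies, one-way sensitivity
analysis, and a triangular-distribution probabilistic sensitivity
analysis (PSA) with cost-effectiveness acceptability curve (CEAC) and
expected value of perfect information (EVPI).

## The model

A cohort enters primary care at age 20. Each year, a living person is
depressed with the age-specific 12-month probability `p_dep(a)`
(general-population prevalence × 1.74, the primary-care enrichment
factor) or well; everyone faces the age-specific all-cause death
probability `q(a)`. Five strategies are compared:

1. no screening + usual care (status quo),
2. PHQ-2/9 screening + usual care,
3. PHQ-9 screening + usual care,
4. PHQ-2/9 screening + collaborative care,
5. PHQ-9 screening + collaborative care.

Two-stage screening administers the PHQ-9 only to PHQ-2 positives, so
jointly `se = se₂·se₉` and `sp = 1 − (1−sp₂)(1−sp₉)` (conditional
independence given true status). Detected people — true and false
positives alike — enter treatment with probability 0.61; treatment is
*adequate* with probability 0.75 under collaborative care vs 0.44 under
usual care; adequately treated depression remits with probability 0.67.
A remitted year accrues utility 0.76 instead of 0.52 (well = 1.0), and
its lost-productivity cost ($2,584/yr) is avoided. Screening costs are
built from clinician wages and administration minutes, adjusted for the
expected PHQ-2 positive rate. The excess of an intervention arm's
remitted fraction over the status-quo cascade is subtracted from the
next year's depression probability (early treatment reduces relapse).
Costs (2015 USD) and QALYs are discounted at 3%/yr:

```
E[Σ_t (1+r)^(−t) · S(t) · x_t],    x_t ∈ {cycle cost, cycle utility}
```

The fully incremental analysis orders strategies by effectiveness,
removes dominated and extendedly dominated arms until the incremental
cost-effectiveness ratios (ICER = ΔC/ΔE) increase strictly along the
frontier. The PSA samples every registered input from a
triangular(low, mode, high) distribution.

## Worked example

```sh
depscreen-cea run --out out/run
```

runs all five strategies on the shipped inputs and the calibrated
synthetic age schedule, and prints:

```
                             strategy     cost  qalys  incremental_cost  incremental_qalys     icer               status
             No screening; usual care 11870.58  24.19               NaN                NaN      NaN          on_frontier
        PHQ-2/9 screening; usual care 12731.42  24.34            860.84               0.15   5625.0 extendedly_dominated
          PHQ-9 screening; usual care 15814.96  24.37           3083.54               0.03 104958.0 extendedly_dominated
PHQ-2/9 screening; collaborative care 12441.35  24.57            570.77               0.39   1481.0          on_frontier
  PHQ-9 screening; collaborative care 16821.95  24.62           4380.60               0.04 104972.0          on_frontier
```

Reading the table: over a 20-to-70 lifetime, two-stage screening plus
collaborative care costs $571 more per person than the status quo and
gains 0.39 QALYs — an ICER of roughly $1,500/QALY, far below any
conventional willingness-to-pay threshold. Screening without
collaborative care (arms 2 and 3) is extendedly dominated: a mix of the
status quo and arm 4 would beat it. The PHQ-9-only + collaborative-care
arm buys its extra QALYs at ~$105,000 each (its lower specificity sends
many false positives into treatment).

```sh
depscreen-cea psa --out out/psa --n-draws 2000 --seed 1
```

```json
{
  "n_draws": 2000,
  "seed": 1,
  "plausible_interval": ["cost-saving", "10,331"],
  "ceac_at_reference": 1.0
}
```

i.e. across joint parameter uncertainty the 95% plausible interval of
the ICER runs from cost-saving to about $10,000/QALY, and at a
$40,000/QALY threshold the intervention is preferred in essentially
every draw. `oneway` produces the tornado-style table (the dominant
drivers are the collaborative-care treatment cost and the inclusion of
lost productivity), and `gen-schedule` writes the synthetic age
schedule so it can be inspected or replaced with real life-table and
survey data (`--schedule your.csv` everywhere).

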