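# Methods

## Model structure

`strokecea` evaluates two intravenous-thrombolysis strategies for acute
ischemic stroke — tenecteplase 0.25 mg/kg versus alteplase 0.9 mg/kg — from a
healthcare-payer perspective over a 10-year horizon.

The first model year is a decision tree. Each arm carries its acute treatment
cost (drug, administration, and for large-vessel-occlusion populations an
expected endovascular-thrombectomy cost) and a 90-day outcome distribution on
the modified Rankin Scale, collapsed to five states:

| state | meaning |
|---|---|
| mRS 0–1 | excellent functional outcome |
| mRS 2–3 | moderate functional outcome |
| mRS 4 | severe disability |
| mRS 5 | bedridden / constant care |
| dead | absorbing |

The collapse follows the observation that mRS 2 and 3 have similar
health-related quality of life while mRS 4 and 5 are markedly worse and
costlier. Early (≤90-day) mortality is folded into the 90-day distribution's
dead entry and is not modelled as a separate event; symptomatic hemorrhage and
other safety events enter only through those distributions.

From 90 days the cohort advances through a 90-day→1-year transition matrix
(patients can still improve or deteriorate in the first year) and then through
annual cycles of a stabler matrix. Each annual cycle the disease-specific
matrix is merged with the age-specific background mortality q of the general
population by independent competing risks, `d' = 1 − (1 − d)(1 − q)`, with the
surviving destinations rescaled proportionally so rows stay stochastic. The
cohort's age at the start of the interval ending at year t is
`start_age + t − 1`. The annual matrix is assumed **not** to already contain
general-population mortality; if a user supplies matrices that do, the life
table should be set to zeros (this is a declared calibration flag, not a
guess the engine makes silently).

### EVT branch

For LVO populations the acute cost adds
`P(eligible) × (1 − P(forgone)) × EVT cost`, where the forgone fraction is the
share of eligible patients who recanalise early after thrombolysis and need no
thrombectomy. The 90-day distribution is the corresponding mixture of the
with-EVT and no-EVT branch distributions; when a single trial-level outcome
distribution is supplied it is used for both branches, so EVT then affects
costs only.

## Accrual and discounting

QALYs multiply state occupancy by per-state utilities (death anchored at
exactly 0); costs multiply occupancy by per-state annual healthcare costs,
plus the undiscounted acute cost at entry. The first year is duration-weighted
between the two measured time points: 0.25 y at the 90-day distribution plus
0.75 y at the 1-year distribution — the least-assumption interpolation given
only those two measurements. Base-case discount rates are 4 %/year for costs
and 1.5 %/year for effects (Dutch guideline).

Discount timing is genuinely underdetermined by the published description, so
it is an explicit convention switch used consistently everywhere:

* `start_of_interval` (default): year-1 accruals undiscounted; the interval
  ending at year t (t ≥ 2) discounted at exponent t − 1;
* `end_of_interval`: every exponent shifted one year later.

No half-cycle correction is applied; the convention switch is the sanctioned
knob for reconciling against outputs produced under the other timing.

## Economics

Increments are intervention − comparator. The ICER ΔC/ΔE is reported as a
ratio only when both increments share a sign (the southwest quadrant is
flagged, since lower ratios are better there); cheaper-and-no-less-effective
is *dominant*, the reverse *dominated*, and a zero increment pair
*equivalent*. Incremental net monetary benefit is `ΔE × λ − ΔC`, reported at
λ = €50,000 and €80,000 per QALY by default.

## Sensitivity analysis

**One-way (tornado).** Each configured parameter is set to ±20 % of its base
value and the whole pipeline is re-run; bar endpoints are genuine model
evaluations. Perturbing one component of a probability vector renormalises the
remaining components by `(1 − c′)/(1 − c)`. Several targets may be grouped
under one id and moved by the same factor (a correlated both-arm sweep); the
shipped configuration lists the 90-day mRS 0–1 and death components **per
arm**, because a correlated ±20 % sweep of two nearly identical proportions
(0.369 vs 0.348) cancels almost completely in the increments and produces a
near-zero bar — the per-arm sweeps are what reveal how sensitive the decision
is to the outcome and mortality proportions.

**Probabilistic.** Parameters are drawn per Monte-Carlo iteration: Dirichlet
over whole 90-day outcome vectors (concentration = mean × effective sample
size, default 100 — an explicit, tunable stand-in for unpublished standard
errors), beta for utilities and single probabilities, gamma for costs, both by
method of moments from (mean, SE). When only a point estimate exists the SE
defaults to `0.2 × mean / 1.96`, i.e. the one-way ±20 % range read as a 95 %
CI, keeping deterministic and probabilistic ranges coherent. Infeasible
moment-matching (SE too large for a beta mean) is a configuration error naming
the parameter; invalid draws raise rather than being silently skipped. Each
draw i uses `numpy.random.default_rng([seed, i])`, so results are
bit-reproducible for a seed and enlarging n never reshuffles earlier draws.
The acceptability curve reports, per threshold λ, the fraction of draws with
positive INMB.

**Scenarios.** Scenarios are data: named sets of dotted-path overrides applied
to a deep copy of the base spec and re-validated. The six shipped scenarios
cover real-world register outcomes, equal 4 % discounting, a 4-year Markov
horizon (5 model years total), and three LVO populations (one anchored at
90-day mortality 19.4 %/21.2 %, one at 9.9 %/17.8 % with 22 %/10 % of EVT
forgone after early recanalisation, and the latter population above age 80 on
the short horizon).

## The trial-anchored configuration and what it is not

`fixtures.paper_base_fixture()` assembles the base case from publicly printed
values — 90-day mRS 0–1 36.9 %/34.8 % and death 15.1 %/15.6 % (tenecteplase/
alteplase), drug prices €987/€791, doses 0.25/0.9 mg/kg, age 74, weight 78 kg,
discounting 4 %/1.5 %, thresholds €50k/€80k, n = 10,000 PSA iterations — plus
declared assumptions for everything the public record does not print:

* the mRS 2–3/4/5 split of the remaining 90-day mass (62/25/13 % of the
  remainder, identical shape in both arms);
* utilities 0.89/0.71/0.33/0.05 (Dutch EQ-5D-5L mRS literature values);
* annual post-stroke costs €4,000/€12,000/€40,000/€60,000 per state
  (nursing-home-dominated upper states);
* both transition matrices, an IVT administration cost of €950 per arm, an
  EVT cost of €9,500, and a Gompertz life table
  `q(a) = 0.0095·e^{0.095(a−65)}` approximating Dutch general-population
  mortality.

Every value carries a `paper-text` or `assumption` tag in the spec's
provenance block, and the emitted YAML makes replacing assumption cells with
real supplementary-table values a drop-in edit. Consequently the fixture
reproduces the *structure* and the *directional* findings of the published
analysis (dominance in the base case, positive INMB across all scenarios,
outcome/mortality proportions as the dominant tornado bars, higher
tenecteplase total costs in the strong-effect LVO scenario, driven by longer
survival), while absolute cost totals and increment-level quantities depend on
the assumed annual-cost levels and should not be read as a reproduction of the
supplementary-table parameterisation. Passing tests therefore demonstrate
engine correctness and directional robustness, not agreement with unpublished
inputs.

## Numerical choices

* Probability rows must sum to 1 within 1e-9; rows off by ≤ 1e-6 (published
  rounding) are renormalised once on input; values > 1 in probability slots
  are rejected outright to catch percent/proportion mix-ups.
* Vial pricing is an exact exhaustive search over vial-count combinations
  bounded by ⌈dose / smallest vial⌉.
* Utilities are capped at 1 when perturbed upward; dead-state utility and cost
  are exactly 0 by invariant.
* Life-table lookups beyond the last tabulated age reuse the last value; below
  the first tabulated age they are a configuration error.
* Degenerate inputs: a cohort entirely dead at 90 days accrues exactly the
  acute cost and zero QALYs; identical arms compare as `equivalent` with zero
  INMB at every threshold.

## Problem sizes

The shipped analyses use the published design sizes: 10-year horizon (11
distributions per trajectory), 14 tornado parameters, and 10,000 PSA
iterations. Property tests sweep 500 random seeded models (1,000 cohort runs)
and check sampler calibration at 50,000 direct draws.

## Known limitations

* Cohort expectations only: no patient-level simulation, tunnel states, or
  time-varying utilities/costs.
* Two-arm comparisons only; no n-way efficiency frontier.
* No value-of-information analysis and no currency conversion/indexing;
  inputs are assumed already expressed in the target price year.
* The synthetic configuration emulates real parameter tables structurally but
  cannot stand in for them numerically (see above).
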