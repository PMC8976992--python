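# Methods

## Model structure

The model is a deterministic five-state Markov cohort simulation for
esophageal squamous cell carcinoma treatment strategies, evaluated per
stage group (I; II–III). States: no-recurrence, local recurrence,
metastasis, complication, dead. Cycle length 0.5 years, horizon 15
years (30 cycles), cohort entry age 60. The horizon must be an integer
number of cycles; anything else is a configuration error.

The treatment episode itself is not a state: it acts once, at entry,
through the initial distribution — a fraction `p_death_init` of the
cohort dies perioperatively, `p_complication_init` starts in the
complication state, and the rest start in no-recurrence. Local
recurrence and metastasis start empty and are reached only through
transitions.

Transition structure per cycle:

| from | to | probability |
|---|---|---|
| no-recurrence | local recurrence / metastasis / dead | strategy-specific inputs |
| complication | no-recurrence | 1 − `p_comp_to_dead` |
| local recurrence | metastasis / dead | `p_lr_to_met`, `p_lr_to_dead` |
| metastasis | dead | `p_met_to_dead` |
| dead | dead | 1 (absorbing) |

Residuals are stay probabilities; every row must sum to 1 within 1e-12.
The complication state is deliberately transient (one-cycle tunnel):
its occupants model short-run treatment morbidity, and the inputs
provide no long-run complication dynamics to justify a persistent state.

### Structural defaults

The published inputs specify only the no-recurrence exit probabilities.
The downstream states need closure, so the package ships structural
per-cycle defaults chosen to reflect salvage prognosis after local
recurrence and stage-IV prognosis after metastasis:

| parameter | default (per 6-month cycle) | meaning |
|---|---|---|
| `p_comp_to_dead` | 0.00 | complication resolves, no excess death |
| `p_lr_to_met` | 0.25 | local recurrence progresses to metastasis |
| `p_lr_to_dead` | 0.20 | death from local recurrence |
| `p_met_to_dead` | 0.50 | death with metastatic disease (median survival ≈ 1 y) |

These are package defaults, not published estimates; every CSV report
flags them in its header and each is overridable per strategy in the
parameter document. Under these defaults all six bundled parameter sets
leave more than 95 % of the cohort dead at the horizon, consistent with
the model's design premise.

## Rewards and discounting

Costs (US$ 2021), life-years and QALYs accrue at cycle start on the
occupancy entering the cycle, discounted at
`(1 + r)^(−t·Δ)` with r = 0.03 per year. The one-time treatment cost
falls at cycle 0 undiscounted (no time has elapsed). A terminal-care
cost, when configured, attaches to each cycle's new entrants to the
dead state at that cycle's discount factor, including the perioperative
deaths at entry; its default is 0. The dead state accrues zero QALY;
utilities apply only to alive states (stage-specific utility for
no-recurrence, complication and local recurrence; the stage-IV utility
0.75 for metastasis). Whether the published utilities embed
treatment-specific disutility is unknowable from the inputs; the fields
are independently configurable per strategy for exactly that reason.

An optional half-cycle correction (off by default) replaces cycle-start
accrual with the mean of the two boundary occupancies discounted at
mid-cycle. It is a sensitivity flag, not the base case: the reference
analysis this package reproduces gives no indication of using one.

Transition inputs are treated as per-6-month-cycle probabilities as
given, with no rate conversion; `prob_to_rate` / `rate_to_prob`
(constant-hazard transforms) are provided for users who want to rescale
cycle lengths in sensitivity work.

## Downstream-cost calibration

Published total lifetime costs include diagnosis, follow-up and
terminal care on top of the one-time treatment cost, but only the
latter is itemised per strategy. The bridge is a uniform per-cycle cost
`c` applied to all alive states. Total discounted cost is affine in
`c` — `total(c) = fixed + c · Σ_t δ(t)·alive(t)` — so `c` solves in
closed form, and refitting reproduces any attainable target to 1e-9
relative (targets below the fixed component are rejected). Calibration
is performed at base case; in sensitivity runs the fitted `c` is held
and total costs respond to occupancy changes, which is the intended
behaviour of a per-cycle resource cost.

Because the true per-strategy downstream internals are unpublished, the
calibrated model reproduces published *totals* exactly but not
published QALY/LYG decompositions; those depend on the original
authors' unprinted inputs. Model validity therefore rests on structural
checks (below), not on matching those internals.

## Incremental analysis

Strategies are compared on discounted cost and QALYs. Strong dominance
(another strategy costs no more, yields no less, one strict) is removed
first; extended dominance then iteratively prunes candidates whose ICER
against the previous frontier member is at least the ICER of the next
member against them (the weak inequality also prunes collinear points,
keeping frontier ICERs strictly increasing — an enforced invariant).
The reference is the cheapest frontier member; ICERs are computed
between adjacent frontier members. An undefined ICER (zero QALY
difference) is an explicit `None`, never a sentinel number.

Classification against willingness-to-pay: ICER ≤ $5627/QALY (1× GDP
per capita) → `cost_effective_1x`; ≤ $16,881 (3×) →
`cost_effective_3x`; otherwise `not_cost_effective`; bounds inclusive.
A negative ICER with a QALY gain is `dominant`, as is a reference
strategy that strongly dominates every competitor. ICERs are rounded to
one decimal in reports only; all comparisons use unrounded values.

**Preference rule.** Sensitivity analyses need a single "preferred
strategy" per scenario. The rule, made explicit here because the
reference analysis states only outcomes: walk the frontier in
increasing QALY order and accept each member whose ICER is at most the
1×GDP threshold; the preferred strategy is the most effective accepted
member, falling back to the cheapest frontier member. This reproduces
the reference base-case preferences in both stage groups.

## Sensitivity analysis

One-way: each published range (degenerate ranges for parameters
without one) is applied to its strategy — or to every strategy for the
stage-level utility ranges — with all else at base case, and the full
pipeline is rerun at both endpoints. When the endpoint preferences
disagree, the switch value is located by bisection to 1e-6 relative
tolerance (≤80 iterations). A range printed in descending order is
stored sorted with a provenance note; bounds are interval endpoints, so
order carries no information.

Two-way cost analysis: two strategies' treatment costs sweep a grid;
traces are cost-independent and computed once, only reward accumulation
repeats per cell. The breakeven along each axis (other strategy at its
base cost) is the largest cost at which the axis strategy is preferred,
refined by bisection between the bracketing cells — exact here, because
total cost is affine in treatment cost with slope 1.

## Synthetic data

The generator emulates the *structure* of the published inputs:
probabilities uniform within configurable intervals (uniform, not
beta/gamma, because the deterministic sensitivity design uses interval
endpoints, not distributions), row-sum feasibility enforced by bounded
rejection, right-skewed lognormal costs, utilities uniform in bounds;
bit-reproducible given a seed. It does not emulate real-data features
such as correlated parameters, age-dependent background mortality, or
sampling uncertainty in the source estimates — so passing fuzz tests
demonstrates structural robustness of the pipeline, not clinical
realism of any sampled scenario.

## Verification

- **Microsimulation oracle**: an independent individual-level Monte
  Carlo simulation (200,000 patients in the acceptance layer; a smaller
  run per-module) samples state paths from the same transition rows and
  must agree with the cohort trace within 3 standard errors, state by
  state and cycle by cycle, and on undiscounted life-years.
- **Closed forms**: geometric decay of the no-recurrence state when
  complication reflux is removed (1e-12); the 15-year discounted
  annuity for an immortal cohort; zero-discount equivalence of
  discounted and undiscounted outcomes (1e-12).
- **Frontier oracle**: for up to six strategies, the frontier from the
  sequential algorithm equals the one from exhaustive pairwise-mixture
  enumeration.
- **Monotonicity**: raising any single to-dead probability never
  increases discounted life-years or QALYs.
- **Calibration recovery**: the fitted per-cycle cost recovers a
  planted value to 1e-9 relative.

## Problem sizes

The cohort model is a 30-step iteration of a 5×5 matrix product, so all
deterministic analyses are effectively instantaneous; the test suite
uses 1000 fuzz seeds for the generator, 60,000–200,000 patients for the
microsimulation oracle, and full-range one-way analyses over all 22
bundled ranges.

## Known limitations

- No age-dependent background mortality; all mortality is
  disease- or treatment-attributed. Over a 15-year horizon from age 60
  this overstates survival slightly in low-mortality states.
- The four structural probabilities are assumptions; conclusions that
  hinge on post-recurrence dynamics should vary them explicitly.
- Downstream costs are uniform across alive states after calibration;
  state-specific cycle costs are supported but have no published
  targets to calibrate against.
- Parameters vary one at a time in sensitivity analysis; no
  probabilistic (joint) uncertainty analysis is included, mirroring the
  deterministic design the package reproduces.
- Utilities are stage-constant; no time-dependence or age decrement.
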