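# esocea

A Markov cohort cost-effectiveness model for treatment strategies in
esophageal squamous cell carcinoma (ESCC), built for health economists
comparing curative interventions by disease stage: endoscopic mucosal
resection (EMR), EMR followed by ablation, and esophagectomy in stage I;
esophagectomy, chemoradiotherapy (CRT), and CRT followed by surgery in
stages II–III.

## The model

A cohort of 60-year-old patients is distributed over five health states
— *no-recurrence*, *local recurrence*, *metastasis*, *complication*,
*dead* — and redistributed every 6-month cycle by a strategy-specific
row-stochastic transition matrix **P** over a 15-year horizon (30
cycles, by which point >95 % of every cohort has died):

```
x_{t+1} = x_t P,   x_0 = (1 − p_comp − p_death, 0, 0, p_comp, p_death)
```

Treatment enters through the initial distribution (per-episode
complication and perioperative-death probabilities) and through the
no-recurrence exit probabilities. The complication state is transient
(occupants return to no-recurrence after one cycle unless fatal); dead
is absorbing. Per-patient rewards accumulate at cycle start with a 3 %
annual discount rate on both costs (US$ 2021) and outcomes:

- **LYG** = Σ_t δ(t) · alive(t) · Δ, with δ(t) = 1.03^(−t·Δ), Δ = 0.5 y
- **QALY** = the same sum with each alive state weighted by its utility
  (0.693 in stage I, 0.76 in stages II–III, 0.75 for metastasis)
- **Cost** = one-time treatment cost + per-cycle downstream costs
  (diagnosis/follow-up/terminal care), the latter calibrated so the
  model reproduces given total lifetime costs (a closed-form linear
  solve, since total cost is affine in the uniform per-cycle cost).

Strategies are then ranked by incremental cost-effectiveness ratio
(ICER = ΔC/ΔE) after removing strongly and extended-dominated options,
and classified against Iran's willingness-to-pay thresholds of 1–3×
GDP per capita ($5627–$16,881 per QALY). One-way deterministic
sensitivity analysis reruns the whole pipeline at each parameter's
published low/high bound, locating preference switches by bisection; a
two-way sweep over two strategies' treatment costs maps
preferred-strategy regions and breakeven costs.

## Worked example

The base-case analysis for stages II–III, with downstream per-cycle
costs calibrated to the bundled total-cost targets:

```sh
esocea base-case \
  --params src/esocea/data/stage23_base.yaml \
  --calibrate-to src/esocea/data/basecase_totals.yaml \
  --out out/stage23
```

`out/stage23/incremental.csv` (abridged):

| strategy | total_cost | qaly | lyg | icer_per_qaly | status | classification |
|---|---|---|---|---|---|---|
| CRT | 4738.9 | 2.147 | 2.828 | | reference | cost_effective_1x |
| CRT_surgery | 6707.0 | 3.172 | 4.175 | 1921.1 | on_frontier | cost_effective_1x |
| esophagectomy | 7622.8 | 2.213 | 2.917 | | strongly_dominated | dominated |

Reading: esophagectomy costs more ($7622.8) and yields fewer QALYs
(2.213) than CRT followed by surgery, so it is strongly dominated. CRT
followed by surgery gains 1.02 QALYs over CRT at $1921 per QALY — well
under the $5627 1×GDP threshold, hence cost-effective. In stage I
(`--params src/esocea/data/stage1_base.yaml`) EMR has the lowest cost
and highest QALY simultaneously and dominates both alternatives.

Other subcommands: `esocea sensitivity` (one-way analysis over a ranges
document), `esocea cost-grid` (two-way treatment-cost regions with
breakeven costs), `esocea synth` (seeded synthetic parameter documents).
Every output directory contains a `manifest.json` with the settings
snapshot and input checksums; CSV headers flag the structural transition
probabilities that are package defaults rather than published estimates.

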