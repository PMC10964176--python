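# briskwalk

A pilot-trial analysis toolkit for an app-based brisk-walking intervention in
people living with and beyond cancer. The package re-implements, as tested
and reusable code, the quantitative pipeline of a two-arm feasibility RCT:

- **Synthetic trial data** (`briskwalk.synthetic`) — per-patient
  participant-flow ledgers, cohort tables and event-level activity-monitor
  traces with known ground truth, including presets that encode the pilot's
  published participant flow (1037 screened → 90 randomised) and cohort mix.
- **Accelerometry** (`briskwalk.accelerometry`) — processes event-level
  posture/stepping records (sedentary, standing, stepping bouts with step
  counts) into the trial's intended primary outcome: minutes of brisk
  walking per week, with brisk walking defined as cadence > 100 steps/min
  over 60-s epochs, sleep/wake delineation with a 200-step waking rule,
  full-24 h valid-day filtering and a 3-valid-day inclusion minimum.
- **Feasibility** (`briskwalk.feasibility`) — the pre-specified
  feasibility/acceptability rates (interest, enrolment, retention, call
  receipt, app use …), recruitment-bias comparison against aggregate site
  data, and fidelity of behavioural-support calls against a 25-item
  behaviour-change-technique checklist with 80% double-coding agreement.
- **Trial design** (`briskwalk.design`) — the phase-III sample-size
  calculation: a two-sample unequal-variance (Welch/Satterthwaite) power
  equation solved by noncentral-*t* iteration, with Monte-Carlo
  verification.
- **Health economics** (`briskwalk.healthecon`, `briskwalk.psa`) — a
  lifetime three-state Markov cohort model (alive, dead of cancer, dead of
  other causes) linking a MET-h/week activity change to cause-specific
  mortality via hazard ratios, discounted QALYs and NHS-perspective costs,
  plus probabilistic sensitivity analysis, CEAC, and EVPI/EVPPI value-of-
  information estimators.

## The statistics at the core

**Sample size.** For arm means differing by δ (h/day of brisk stepping),
control SD σ₁ and intervention SD σ₂ = σ₁√r (variance ratio r), the
per-group size n solves the Welch power equation

    power = P( |T'| > t_{1−α/2, ν} ),   T' ~ noncentral t(ν, ncp),
    ncp = δ / √(σ₁²/n + σ₂²/n),  ν = Satterthwaite df,

iterated from the normal-approximation start
n₀ = (z_{1−α/2}+z_{power})²(σ₁²+σ₂²)/δ². The randomised total is 2n
inflated by 1/(1−dropout) and rounded up to the next even integer.

**Decision model.** Annual-cycle cohort model from the start age to age 100.
Cause-specific hazards are combined competing-risk style (rates summed,
deaths partitioned pro rata); the intervention multiplies each hazard by
hr^ΔMET while the effect persists. QALYs are
Σ u(age)·S̄(t)·(1+ρ)^−(t−½) with mid-cycle occupancy S̄ (half-cycle
correction) and a per-decade multiplicative utility decrement. EVPI at
willingness-to-pay λ is E[max(0, INB)] − max(0, E[INB]) with
INB = λ·ΔQALY − ΔCost; single-parameter EVPPI uses the regression
(smoother) method.

## Worked example

```bash
python examples/sample_size.py
```

```
per-group n before dropout : 212
randomised total (even)    : 472
achieved power at n=212   : 0.9007
effect in minutes          : 6 min/day = 42 min/week
Monte-Carlo power check    : 0.903
```

212 participants per arm give 90.07% power for the 0.10 h/day effect; after
10% dropout inflation the confirmatory trial must randomise 472 people. The
Monte-Carlo line re-derives the power by simulating 10,000 Welch tests.

```bash
python examples/cost_effectiveness.py
```

```
MET-h/week gained : 3.01
incremental cost  : £62.52
incremental QALYs : 0.0772
ICER              : £810/QALY
NMB at £20k/QALY  : £1481
...
EVPI at £20k/QALY : £56.57 per person
EVPPI[delta_met] : £34.63
EVPPI[intervention_cost] : £0.00
```

A 42 min/week brisk-walking gain converts to 3.01 MET-h/week; under the
illustrative hazard-ratio and utility defaults the intervention costs
£62.52 and gains 0.0772 discounted QALYs. The EVPI line prices the expected
loss from deciding under current uncertainty; almost all of it is
attributable to the effectiveness parameter, none to the intervention cost.

The other examples (`feasibility_rates.py`, `process_accelerometer.py`,
`simulate_trial.py`) print the pilot's feasibility table from the ledger
preset, a single participant-week processed end to end, and a full synthetic
two-arm study with its effect recovered by the pipeline.

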