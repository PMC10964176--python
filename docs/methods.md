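# Methods

This note documents the models and procedures implemented in `briskwalk`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## Accelerometry processing

The input is an event-level record from a thigh-worn monitor: ordered,
non-overlapping bouts classified sedentary / standing / stepping, with a
step count per stepping bout. Processing follows four stages.

**Sleep/wake delineation.** A two-state heuristic, not a clone of any
proprietary device pipeline. Maximal contiguous sedentary runs of at least
3 h (`AccelConfig.sleep_block_min_s`) seed "sleep" — here meaning *time in
bed*, not biologically defined sleep. Each seed is then grown outward over
adjacent non-standing events while the steps accumulated since leaving the
seed remain below 200 (`min_waking_steps`): a candidate waking period needs
at least 200 steps to count as waking, so short night-time bed exits
(bathroom trips) are absorbed into the sleep block, while a genuine active
morning ends it. Standing always ends a block, on the reasoning that
standing means out of bed. The 200-step threshold is the waking-delineation
setting used in the trial's device processing; the 3 h seed length is this
package's choice — long enough that television-watching rarely seeds sleep,
short enough to catch fragmented nights. When a participant log sheet is
supplied, any day where the algorithmic bed/rise transition differs from the
logged one by more than 1 h is corrected to the logged clock time (the 1 h
threshold mirrors the scale of mis-coding the trial reported); when the
algorithm finds no transition at all on a logged day — typically the final
evening, where the recording ends before the night completes — the logged
time is applied directly.

**Valid days.** A day is valid only with complete 24 h wear (event coverage
of exactly 86,400 s); a participant is included only with ≥ 3 valid days.

**Cadence epochs.** Steps are laid onto 60-s epochs aligned to civil
midnight. The epoch length is fixed by the outcome definition (steps *per
minute*); a bout spanning an epoch boundary is apportioned pro rata by
time, i.e. at the bout's constant within-bout cadence — uniformity is the
only information-free choice given that within-bout step timing is not
recorded. A waking epoch with more than 100 steps is a brisk minute
(strict inequality); a waking epoch with ≥ 1 step is a walking minute.
Apportionment conserves steps exactly up to floating-point rounding
(< 1 step/day), verified against a per-second brute-force expansion.

**Weekly outcome.** The person-level outcome is the mean over valid days
scaled to 7 days. The source analysis does not state its aggregation rule;
mean × 7 was chosen because it is robust to unequal valid-day counts
(summing over a 5-valid-day week would understate activity). Group
summaries are medians with 25th/75th percentiles, reflecting the skewness
of activity data.

## Feasibility rates

Every rate is carried as (numerator, denominator, percentage); percentages
use round-half-up, to integer percent by default and to one decimal where
the trial reported one decimal. A zero denominator yields an "undefined"
outcome, never 0%. One published cell (app download, 42/44) is printed in
the source as 96% although the ratio is 95.45%; this package reports 95%
and the raw ratio rather than forcing the printed value. Call-fidelity
scoring is the percent of the 25-item behaviour-change-technique checklist
delivered per call; double-coding agreement is the percent of matching
indicators per transcript, with transcripts below 80% (discrepancy
exceeding 20%) flagged for consensus.

## Sample-size calculation

Two-arm comparison of mean daily hours of brisk stepping with unequal
variances: control SD 0.20 h/day, intervention variance four times larger.
The per-group n solves the two-sided Welch power equation with noncentral-t
power at Satterthwaite degrees of freedom, iterating the integer n from the
normal-approximation closed form to the exact boundary. The t-based
solution (212/group, total 472 after 10% dropout inflation and even
rounding) is used rather than the z-based one (211/group, total 470)
because the t-based iteration reproduces the trial's published total; the
original software's internal quantile choice is not documented, so this is
an inference, not a citation. Dropout inflation divides the total by
(1 − dropout) and rounds up to the next even integer to keep arms equal.
`simulate_power` verifies the analytic solution by direct Monte Carlo
(vectorised Welch tests on normal draws); note the analytic power treats
the Satterthwaite df as fixed at its expected value, an approximation
accurate to well under half a percentage point at these sizes.

## Lifetime cost-effectiveness model

A three-state Markov cohort model — alive, dead of cancer, dead of other
causes — with annual cycles from the cohort start age (default 63) to age
100. Mortality is the only pathway by which activity affects outcomes,
matching the evidence linking MET-h/week of activity to cancer and
other-cause mortality; richer structures (recurrence, progression states)
are an explicit extension point.

- **Hazards.** Other-cause mortality comes from a user-supplied lifetable
  (`age, annual_death_probability`) or an illustrative Gompertz schedule
  (defaults b = 2×10⁻⁵, c = 0.098 per year of age, giving ≈ 1% at 63 and
  ≈ 6% at 80). No default is presented as a published value. The cancer
  excess hazard is a constant annual rate (default 0.02/year).
- **Effect.** The intervention's activity change ΔMET (MET-h/week, via
  `met_conversion` with configurable MET intensities, defaults brisk 4.3 /
  slow 3.0) multiplies each cause-specific hazard by hr^ΔMET — the
  conventional log-linear dose-response — for `effect_duration` years
  (default 5), a step function so that effect-persistence scenarios are a
  single knob; an exponential-decay variant was considered and left out of
  the default surface.
- **Competing risks.** Annual cause-specific rates are summed; the cycle
  death probability is 1 − exp(−h·Δt); deaths are partitioned in
  proportion to the rates. For constant hazards this reproduces
  exponential survival exactly.
- **QALYs and costs.** Discounted at 3.5%/year (both), half-cycle corrected
  using mid-cycle occupancy at discount exponent t − ½. Utility is the
  baseline EQ-5D index with a multiplicative decrement per decade of age
  (default 0.97/decade). The intervention arm incurs the per-person
  intervention cost at cycle 0 (£62.52, the trial's micro-costing total,
  stored as a constant because its components are not individually
  published; `build_intervention_cost` reproduces the costing *structure* —
  direct materials, 55 min of nurse delivery time, a training day amortised
  over 10 nurses × 200 patients/year × 3 years — for user-supplied unit
  costs) and an optional annual resource-use offset per alive person-year,
  representing the between-arm difference in NHS resource use (default 0).

Verified invariants: state occupancies sum to 1 (≤ 10⁻¹² error), survival
is non-increasing, the QALY engine matches the closed-form annuity in the
immortal-cohort limit to 10⁻⁹, and a null effect leaves ΔQALY = 0 and
ΔCost equal to the intervention cost exactly.

## PSA and value of information

Parameter uncertainty uses conventional families: normal for the activity
effect, lognormal for hazard ratios (parameterised by natural-scale
mean/SD), beta for utilities, gamma for costs, independent by default.
Draws violating parameter domains (e.g. a utility above 1) are rejected and
counted rather than clipped. Credible intervals are percentile-based
(2.5th/97.5th). The CEAC is the fraction of draws with positive incremental
net benefit per threshold. EVPI is E[max(0, INB)] − max(0, E[INB]) with the
comparator normalised to zero. Single-parameter EVPPI uses the regression
method — a lowess smoother of INB on the parameter draws estimates the
conditional expectation, and the EVPI formula is applied to the fitted
values — chosen over nested Monte Carlo for desk-scale runtime; a nested-MC
verification mode (`evppi_nested`) is provided. Scenario analysis re-runs
the PSA under perturbations (effect multiplier, effect duration, cost
scaling, resource offset, baseline-mortality multiplier) with common random
numbers, so a scenario identical to base reproduces base results exactly.
Population scaling of per-person VOI is single-year by default (per-person
value × annual incident patients), with a discounted multi-year option.

The published base-case outputs of the source analysis (£69 incremental
cost, 0.0019 QALYs, ICER £36,475, 37% probability cost-effective, £18.83
EVPI) depend on supplementary parameter values that were not published;
they are therefore *not* reproduction targets of this package. The tests
instead pin down the machinery with constructed fixtures (exact two-point
EVPI, an exactly-37% CEAC fixture, EVPI ≥ EVPPI ≥ 0 sweeps).

## Synthetic-data generator

The generator defines the study conditions for every pipeline test.

- **Ledger.** Per-patient boolean stage flags realised by seeded sampling
  so aggregates equal the specification exactly; flags are nested along the
  funnel, making funnel monotonicity hold by construction. The preset
  encodes the pilot's published flow (1037 screened, 577 sent letters, 369
  willing, 148 sent information sheets, 93 consented, 44/46 randomised, 87
  with any follow-up, 43 first and 39 second calls, 42 app downloads, 39
  asked about app use, 33 still using).
- **Cohort.** Ages normal (63 ± 11, truncated to 18–100), sex 52/48,
  cancer type 40/40/20 breast/prostate/colorectal, stages 32/33/27/8%,
  EQ-5D normal clipped to [0, 1] (0.80 ± 0.12), baseline weekly brisk
  minutes lognormal matched to median 181 with IQR 116–363. The published
  quartile triple is not log-symmetric, so the two-parameter lognormal
  tracks the IQR only loosely; these are deliberately loose targets since
  no generative distribution was published.
- **Activity traces.** Built on a one-minute lattice: each day is sleep
  (23:00–07:00), sitting (≈10 h), standing, and stepping bouts of 5–15
  whole minutes with one integer cadence per bout — brisk bouts truncated
  to 101–140 steps/min, slow bouts to 30–99 — so a wear-complete day tiles
  86,400 s exactly and the true brisk minutes per day are known exactly
  (cadence classes never cross the 100 steps/min threshold within a bout).
  Daily brisk minutes are truncated-normal: intervention 39 ± 18, control
  27 ± 14 min/day, chosen so the downstream weekly medians land in the
  region of the pilot's follow-up distributions (≈270 vs ≈190 min/week).
  Night-time bed exits (1–2 min, < 200 steps, probability 0.3/night) sit
  well inside the sleep block to exercise the 200-step rule; waking periods
  begin and end standing so the overnight sedentary run is bounded at the
  true bed/rise times. Non-wear days (optional) drop the 13:00–17:00
  events, breaking 24 h coverage. Each participant has an independent RNG
  stream derived from (master seed, participant index), so adding
  participants never perturbs existing traces.

What the generator does **not** emulate: raw 20 Hz signal, posture
misclassification by the device, irregular real-world sleep schedules,
within-bout cadence variation, daytime naps, and questionnaire responses.
Consequently, passing pipeline tests demonstrate correctness of the
*computation* (epoching, thresholding, filtering, aggregation) and
robustness to the modelled perturbations (bed exits, non-wear, boundary
spanning), not robustness to every artefact of real device data.

## Problem sizes and numerical choices

Defaults: PSA K = 10,000 draws (the library default; examples and tests use
2,000 and less, which is ample for the quantities asserted), power
simulation 10,000 replicates, oracle sweeps 100–1,000 random traces, and
synthetic studies of 20 participants/arm — sizes at which every asserted
quantity is stable at the tolerances tested. Ties and degenerate inputs:
a zero feasibility denominator reports "undefined"; an ICER with ΔQALY > 0
and ΔCost < 0 is "dominant", with ΔQALY ≤ 0 and ΔCost > 0 "dominated"; a
degenerate (zero-variance) PSA parameter yields a constant column and an
EVPPI of exactly 0. Seeds are explicit everywhere randomness exists.

## Known limitations

- The sleep/wake heuristic is a simplification; on real data it would need
  validation against annotated records. The final evening of a recording
  cannot be classified without the log sheet.
- The Markov model omits morbidity pathways (recurrence, cardiovascular
  events) by which activity plausibly affects QALYs; it will understate
  benefits if those pathways matter.
- Hazard-ratio dose-response is assumed log-linear in MET-h/week and
  identical across subgroups.
- The equal-allocation (1:1) design is hard-coded in the sample-size
  module.
- PSA distributions are independent; correlated parameter sets (e.g. from
  a multivariate posterior) are not supported.
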