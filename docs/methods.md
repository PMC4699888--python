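# Methods

## Model overview

`hivsim` is an individual-level (first-order Monte Carlo) state-transition
model with a one-month cycle and a lifetime horizon (death or age 100,
whichever first; a finite horizon in months can be configured, in which case
survivors are censored without a death cost). Each patient carries tracked
attributes — age, sex, CD4 count, suppression status, treatment-line
position, INI-resistance flag, opportunistic-infection (OI) state and
history — and accrues costs and quality-adjusted life years month by month.
Cohort outputs are means over independent patients with Monte Carlo standard
errors.

Within a month, events are applied in a fixed contract order:

1. death draws (HIV excess tested first, then background),
2. OI resolution, then at most one new OI onset,
3. virologic evaluation (week-48 endpoint at month 12 on a line; monthly
   late-failure risk for suppressed patients after it),
4. adverse-event (AE) discontinuation,
5. line transition (resistance draw at a first-line virologic exit),
6. CD4 update,
7. cost/QALY accrual with discounting.

The death month is inclusive: a dying patient accrues that month's ART,
routine care, tests and utility at month-start state (OI onset/resolution
excepted, which still run so an OI and death cost can coincide) plus the
one-off death cost. This is the convention the scripted-path ledger tests
pin down; there is no half-cycle correction, whose bias is negligible at
monthly resolution.

## Treatment-line algorithm

Line 1 is the study regimen plus optimized background therapy (OBT). Exits
are: week-48 non-response (switch at the end of month 12, having accrued 12
months of the line's cost — matching the trial's week-48 endpoint), late
virologic failure (monthly probability 0.76% in weeks 48–96 and 2.75%
thereafter on early lines; 0.88%/2.75% on salvage), or AE discontinuation
(monthly probability, an assumption knob, default 0.25%). The published
late-failure rates are used exactly as printed; the upstream observational
inflation applied to their source values is taken to be already included.
The beyond-week-240 period keeps the 2.75% rate (constant extension — no
published value exists past week 240).

INI resistance can be acquired only at a *first-line virologic* failure
(AE switches never confer resistance: resistance requires replication under
drug pressure). The flag is permanent and selects the successor branch:
without resistance, line 2 keeps the study drug's path (DTG+OBT2.0, or
OBT2.1 in the RAL arm) followed by Salvage 1 and Salvage 2 (four lines);
with resistance, line 2 is the salvage-composition OBT2.2 followed directly
by Salvage 2 (three lines). After the final line fails the patient stays on
that regimen indefinitely, flagged as failing the last line, accruing its
cost. AE discontinuation on the final line is a no-op because no successor
regimen exists; earlier lines can always AE-switch.

The whole algorithm is data: the config's `algorithm` section is an
explicit successor table (labels, priced components, efficacy-block
references), so alternative sequencing strategies run without code changes.

## CD4 dynamics

On suppressive therapy the first-year gain (190/189 cells/µL on line 1 by
arm, 176 on second lines, 118 on salvage) is front-loaded: months 1–2 each
deliver half of two thirds of the annual gain, months 3–11 spread the
remaining third uniformly (the simplest reading of "a slower rate"), so
months 1–11 sum exactly to the annual gain — a conservation property the
suite asserts. Months 12–23 spread the year-2 gain (14), later months the
subsequent annual gain (19). Counts are capped at 1,000 cells/µL.

On any line after the first, the cumulative gain per line is capped at the
gain actually realized on line 1 (`cd4_gain_used_line1`). Consequently a
patient who never suppressed on line 1 gains nothing later — the literal
reading of the subsequent-line cap, which we adopt and flag as deliberately
conservative.

On failing therapy before the last line the count plateaus (no gain, no
decline). Once the last line has failed it declines linearly: 3 cells/µL per
month in the base case (an assumption placed between the two scenario
extremes), a steeper CD4-stratified table (4.5–7 cells/µL/month) in the
worst-case scenario, and zero in the optimistic scenario. The count is
floored at 0.

## Opportunistic infections and mortality

OIs arrive as per-type monthly Bernoulli events (bacterial, fungal,
protozoal, viral, other — fixed order) with CD4-stratum-specific hazards,
multiplied by 2 (configurable) for patients with an OI history. A single
uniform per month is allocated exclusively across types, so at most one
episode starts per month and runs are reproducible; one episode is active
at a time and lasts 3 months (1 month in a scenario). The hazard table is
an assumption calibrated in magnitude so lifetime per-type attack
proportions land in the single-digit-percent range at realistic CD4
trajectories.

Mortality combines an abridged general-population life table (age band ×
sex, assumption) with an annual HIV excess probability by CD4 stratum
(0.25% above 500 cells/µL rising to 12% below 50, assumption), both
converted to monthly probabilities as `1−(1−q)^(1/12)`. The HIV component
is tested first and multiplied by 3 during an active OI. A death during an
episode or within the month after its resolution is recorded as "HIV/AIDS
including OI" and costed with the ≤30-days death cost; the monthly cycle
makes "same or next month after resolution" the closest available
implementation of a 30-day window.

"Progression to AIDS" (for the AIDS and AIDS-free-survival outputs) is a
CDC-like proxy: the first OI or the first month with CD4 < 200 cells/µL,
evaluated at entry as well (a baseline OI history or low count counts as
prevalent AIDS).

## Economics

Six cost components (EUR 2012–2014, no re-inflation): ART (component sum of
the line's priced regimens), routine HIV care (six CD4 strata × OI history,
kept exactly as printed including the 0–50 stratum where the no-history
cell exceeds the history cell), one-off OI episode costs, one-off death
costs keyed by OI recency, laboratory tests (a monthly amortised CD4/VL
schedule, default €18/month, plus a €300 genotype at each virologic
failure — both assumptions; no per-test breakdown is published), and a €400
switch cost per line change (assumption). Utilities are CD4-stratified
(0.830/0.860/0.870/0.900); during an active OI the episode utility
(0.561 bacterial/viral/other, 0.652 fungal/protozoal) *replaces* the CD4
utility, except that the minimum of the two applies so an episode can never
improve a very sick patient's utility. Setting every utility to 1 makes
QALYs equal life years exactly (asserted).

Discounting is tiered: 4%/year to year 30 and 2%/year beyond, compounded
piecewise-continuously so the factor is continuous at the boundary —
`(1.04)^(−m/12)` for months within 30 years, then
`(1.04)^(−30)·(1.02)^(−(m/12−30))`. Discounting is applied monthly with
annual-rate fractional exponents (cycle-consistent, exact at year
boundaries), to both costs and QALYs by default (`apply_to` configurable).
The "reduction of up to 2%" guidance is read as a step to a 2% rate, not a
gradual taper.

## Randomness and pairing

Every uniform is a pure function of `(seed, patient id, month, slot)`
through a SplitMix64-based counter hash: no generator state, a fixed draw
budget of seven event slots per patient-month, and separate baseline slots.
This yields bit-reproducibility independent of execution order, exact
common random numbers across arms (the arm never enters the key), and no
desynchronisation when one parameter is perturbed — the property that makes
one-way sensitivity analyses and the price sweep nearly noise-free (a
cost-only perturbation leaves the QALY delta exactly unchanged, asserted).

Baseline attributes are drawn by inverse-CDF transform of per-patient
uniforms (truncated normal for age, truncated log-normal for CD4), so
truncation is exact, degenerate bounds (min = max) collapse cleanly to a
point mass, and each patient's baseline is identical across arms and
cohort sizes.

## Synthetic cohort: what it does and does not emulate

The generator emulates the *marginal* structure of a treatment-experienced,
INI-naive, multi-class-resistant population entering in virological
failure: age ~ truncated N(43, 10²) years on [18, 75], 68% male, CD4 ~
truncated log-normal (log-mean log 200, log-sd 0.8) on [10, 750] cells/µL,
25% with an OI history, 0% suppressed at entry. All values are assumption
defaults — the source trial's patient-level baseline distributions are not
published. It does not model attribute correlations (e.g. CD4 × OI
history), enrolment-site heterogeneity, or calendar effects; baseline viral
load is carried descriptively but drives no rate, since no published rate
depends on it. Passing tests therefore demonstrate internal correctness and
calibrated incremental behaviour, not agreement of absolute levels with any
real cohort.

## Calibration

The per-failure resistance-acquisition probabilities are not observed; they
are calibrated by bisection so the simulated post-first-line no-resistance
proportion — measured among patients leaving line 1 alive — matches the
reported split (88.72% DTG, 55.84% RAL). Because draws are counter-based,
the measured proportion is a non-increasing, nearly-linear function of the
probability and bisection converges in a few dozen reduced-size
simulations (default 20,000 patients, tolerance 0.5 percentage points; an
unattainable target raises an error reporting the attainable range). The
bundled defaults (0.125 DTG, 0.4844 RAL) come from this procedure; with
them a fresh 50,000-patient first-line run reproduces the targets within
Monte Carlo noise.

## Problem sizes

The reference configuration requests 500,000 patients per arm. The test
suite and examples run 300–50,000 patients: incremental outcomes are
near-deterministic under common random numbers at these sizes, and the
calibration checks use 20,000 (solve) / 50,000 (verify) patients, where the
binomial standard error on the calibrated proportion is ≈0.15 percentage
points. These sizes are the package's own choices for routine verification;
production analyses should scale `--n` up.

## Known limitations

* Absolute outcome levels (life expectancy, lifetime cost, AIDS and
  death-cause proportions) depend on the assumption defaults for the
  unpublished inputs (cohort profile, OI hazards, life table, HIV excess
  mortality, AE rate, test/switch costs, terminal decline). They land in a
  plausible range but are not, and cannot be, reproductions of any
  published table; only the calibrated resistance split is held to a
  quantitative target. Incremental directions are the robust output.
* With the default assumptions the simulated cohort survives longer, and a
  larger share of deaths is HIV-attributable, than published summaries of
  comparable models suggest; both are direct consequences of the assumed
  excess-mortality schedule and long terminal phase.
* The sign of the ICER's sensitivity to subsequent-line prices depends on
  which arm spends more discounted time on those lines, which the
  assumption defaults influence; the sensitivity machinery reports whatever
  the configured inputs imply.
* One OI at a time, a single acute mortality multiplier for all OI types,
  and no AE disutilities (only the switching cost and line change) — all
  matching the modelled scope.
* No probabilistic sensitivity analysis: uncertainty is explored through
  one-way deterministic analyses and structural scenarios only.
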