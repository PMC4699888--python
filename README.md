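# hivsim

Individual-level Monte Carlo microsimulation of HIV treatment sequencing and
cost-effectiveness: dolutegravir (DTG) versus raltegravir (RAL) in
treatment-experienced, integrase-inhibitor (INI)-naive adults with multi-class
resistant virus, from a French collective (direct medical cost) perspective.

The package is aimed at health-economic modellers and HIV researchers who
want a transparent, fully configurable re-implementation of this class of
state-transition model: every input is a plain YAML entry, every random draw
is reproducible, and paired arm comparisons use common random numbers so
incremental results reflect parameters rather than sampling noise.

## The model

Simulated patients progress in monthly cycles through mutually exclusive
health states (with/without an active opportunistic infection, death) while
moving down a treatment-line algorithm:

* **Line 1** — DTG + optimized background therapy (OBT) or RAL + OBT.
  Week-48 virologic suppression is a Bernoulli outcome (70.9% DTG, 63.7%
  RAL); non-responders switch after 12 months. Suppressed patients face a
  monthly late-failure risk (0.76%/month to week 96, 2.75%/month after).
* **Resistance branching** — a first-line virologic failure acquires INI
  resistance with an arm-specific probability calibrated to the reported
  post-first-line status (88.72% / 55.84% without resistance). The flag is
  permanent and selects the successor path: four lines without resistance,
  three with.
* **CD4 dynamics** — on suppressive therapy the count recovers front-loaded
  (two thirds of the first-year gain in two months), is capped at 1,000
  cells/µL, and on later lines cannot cumulatively exceed the first-line
  gain; after the last line fails it declines linearly.
* **Events** — CD4-stratified opportunistic-infection hazards (doubled by an
  OI history, episodes last three months) and mortality combining a
  background life table with CD4-dependent HIV excess.
* **Economics** — monthly ART, routine-care (CD4 × OI-history grid), test,
  switch, OI-episode and death costs; CD4-stratified utilities (0.830–0.900)
  replaced by episode utilities (0.561/0.652) during infections. Costs and
  QALYs are discounted at 4%/year for 30 years and 2%/year thereafter.

The cost-effectiveness summary is the incremental cost-effectiveness ratio

```
ICER = (C_DTG − C_RAL) / (E_DTG − E_RAL)   [EUR per QALY gained]
```

computed from unrounded cohort means, with dominance labels when the deltas
disagree in sign. One-way deterministic sensitivity analysis, structural
scenarios (horizon, OI duration, discount rates, no-resistance world,
terminal CD4 decline) and a DTG price sweep sit on top of the paired runs.

Baseline cohorts are synthetic: the entry distributions (age, sex, CD4,
OI history) emulate a treatment-experienced population entering in
virological failure and are fully configurable; no patient-level trial data
are used. See `docs/methods.md` for every assumption and its default.

## Worked example

```
python examples/01_base_case.py --n 20000 --seed 2015
```

prints:

```
Cohort: 20,000 patients per arm, seed 2015
outcome                              DTG         RAL   increment
life years (undisc.)               21.49       20.20        1.29
life years (disc.)                 13.51       12.93        0.58
QALYs (disc.)                      11.88       11.33        0.55
total cost (EUR)                 475,825     462,264      13,561
  of which ART                   368,069     353,014      15,055
  of which routine care           82,415      82,891        -476
months on first line                39.2        36.3         2.8
no INI resistance (%)              88.98       56.71       32.27
ever AIDS (%)                      93.11       93.69       -0.58

ICER: 24,829 EUR per QALY gained (incremental cost divided by incremental QALYs, unrounded means).
Monte Carlo s.e. on DTG QALYs: 0.0329
```

Read it as: DTG patients live longer (mostly because they acquire INI
resistance far less often after a first-line failure, preserving an extra
effective line), which costs more ART over a lifetime; the extra spend per
quality-adjusted life year gained is the ICER. Absolute levels (life
expectancy, total cost) depend on the documented assumption defaults for
unpublished inputs, so treat them as indicative; the incremental mechanics
are what the package is built to study. The other examples cover resistance
calibration (`02`), the sensitivity tornado (`03`), the price sweep (`04`)
and a fully scripted single-patient audit trace (`05`).

A thin CLI wraps the same pipelines:

```
hivsim run-base --n 50000 --out results/
hivsim run-dsa | run-scenarios | price-sweep ...
```

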