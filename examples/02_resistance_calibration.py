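"""Calibrating the resistance-acquisition probabilities.

The probability of acquiring integrase-inhibitor resistance at a first-line
virologic failure is not directly observed; it is calibrated so that the
simulated post-first-line resistance status matches the reported split
(88.72% of DTG patients and 55.84% of RAL patients leave line 1 without
resistance). This script runs the bisection calibration and verifies the
result on a larger fresh cohort.
"""

from hivsim import calibrate_resistance, default_parameters, perturb, simulate_first_line

params = default_parameters()
targets = {"DTG": 0.8872, "RAL": 0.5584}

probs = calibrate_resistance(targets, params, n=20_000, seed=1234)
print("calibrated per-failure resistance probabilities:")
for arm, p in probs.items():
    print(f"  {arm}: {p:.4f}")

for arm, p in probs.items():
    check = perturb(params, f"resistance/prob_on_failure/{arm}", p)
    res = simulate_first_line(arm, check, n=50_000, seed=1)
    print(f"{arm}: target {targets[arm]*100:.2f}% -> simulated "
          f"{res['no_resistance_pct']:.2f}% no-resistance "
          f"({res['n_exited_alive']:,} first-line exits; "
          f"{res['virologic_exit_fraction']*100:.1f}% of exits virologic)")
print("\nThe DTG arm acquires resistance far less often per failure — the "
      "higher genetic barrier that drives its long-term benefit.")
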