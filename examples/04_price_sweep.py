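"""Threshold analysis on the DTG drug-component price.

Scales the monthly DTG molecule price and re-runs the paired comparison at
each level. Because both runs share random draws, the QALY gain is exactly
price-invariant and the ICER moves monotonically: below some price DTG
becomes dominant (cheaper and more effective).
"""

from hivsim import default_parameters, price_sweep

params = default_parameters()
sweep = price_sweep(params, multipliers=(0.8, 0.9, 1.0, 1.1, 1.2),
                    n=10_000, seed=2015)

print(f"{'multiplier':>10}{'DTG EUR/mo':>12}{'d cost':>12}{'d QALY':>10}{'ICER or label':>16}")
for row in sweep.itertuples():
    label = row.dominance if row.dominance else f"{row.icer:,.0f}"
    print(f"{row.multiplier:>10.1f}{row.dtg_monthly_price:>12.0f}"
          f"{row.delta_cost:>12,.0f}{row.delta_qaly:>10.4f}{label:>16}")
print("\nA 'dominant' label means DTG saves money and adds QALYs at that "
      "price; otherwise the column is the incremental cost per QALY gained.")
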