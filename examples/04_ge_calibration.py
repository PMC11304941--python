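"""Calibrate genotyping-error rates from observed Mendelian-error rates.

The GE rate of a real population is not directly observable, but the
Mendelian-error (ME) rate of its trios is. Simulating populations across
a grid of known GE rates yields a reference line ME = a*GE + b whose
inverse converts an observed ME rate into an estimated GE rate — used to
pick generation-specific filtering thresholds.
"""

from magicphase import SimConfig, calibrate_ge_from_me

grid = [0.01, 0.02, 0.03, 0.04, 0.06]
cal = calibrate_ge_from_me(
    SimConfig(offspring_per_cross=2), grid, n_reps=3, seed=7
)

print(f"fit: ME = {cal.slope:.3f} * GE + {cal.intercept:.5f}\n")
print(f"{'GE in':>8} {'ME measured':>12} {'GE inverted':>12}")
for ge, me in zip(cal.ge_grid, cal.me_values):
    print(f"{ge:>8.3f} {me:>12.4f} {cal.invert(me):>12.4f}")

observed_me = 0.025
print(f"\nan observed ME rate of {observed_me:.3f} implies "
      f"GE ~ {cal.invert(observed_me):.4f}")
# The slope is below 1: only a fraction of genotyping errors produce a
# detectable Mendelian inconsistency within a trio.
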