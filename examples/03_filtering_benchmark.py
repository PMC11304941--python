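"""Benchmark haploblock filtering against genotyping errors.

Sweeps genotyping-error (GE) rates against min-informative-allele
thresholds on paired simulated populations. Without filtering (min=1),
error-induced false haploblocks flood the output at high GE rates;
raising min trades a little recall for a large precision gain.
"""

import numpy as np

from magicphase import (
    FilterConfig,
    SimConfig,
    evaluate_detection,
    run_pipeline,
    simulate_population,
)

GE_RATES = [0.0, 0.02, 0.06, 0.10]
MINS = [1, 2, 3]
N_REPS = 3

print(f"{'GE rate':>8} {'min':>4} {'precision':>10} {'recall':>8} {'F1':>8}")
for ge in GE_RATES:
    for mn in MINS:
        f1s, ps, rs = [], [], []
        for rep in range(N_REPS):
            rates = {g: ge for g in (2, 3, 4)} if ge else {}
            pop = simulate_population(SimConfig(seed=100 + rep, ge_rates=rates))
            res = run_pipeline(pop.pedigree, pop.genotypes, pop.marker_map,
                               FilterConfig(min=mn))
            r = evaluate_detection(res.events, pop.truth)
            ps.append(r.precision); rs.append(r.recall); f1s.append(r.f1)
        print(f"{ge:>8.2f} {mn:>4} {np.mean(ps):>10.3f} "
              f"{np.mean(rs):>8.3f} {np.mean(f1s):>8.3f}")
# At GE=0 filtering only costs recall; at GE=0.10 the raw output is
# dominated by false positives and min=3 recovers usable precision.
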