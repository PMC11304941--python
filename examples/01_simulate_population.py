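"""Simulate a chain-crossing MAGIC population and inspect its truth records.

Eight homozygous founders are chain-crossed to the fifth generation (G4)
over one 30 Mb chromosome with 500 SNPs; each meiosis draws a
Poisson(1.5) number of crossovers. The simulator records every true
breakpoint and the founder line behind every allele.
"""

from magicphase import SimConfig, simulate_population

pop = simulate_population(SimConfig(seed=1))

by_gen = pop.pedigree.by_generation()
print("individuals per generation:", {g: len(ids) for g, ids in by_gen.items()})
print("scored meioses (G2+ children x 2 homologs):", len(pop.truth.breakpoints))
print("true crossovers:", pop.truth.n_true)

child, hom = max(pop.truth.breakpoints, key=lambda k: len(pop.truth.breakpoints[k]))
print(f"example meiosis {child}/{hom}: breakpoints at bp",
      pop.truth.breakpoints[(child, hom)])
founders = pop.truth.founder(child, hom)
runs = sum(1 for a, b in zip(founders[:-1], founders[1:]) if a != b) + 1
print(f"  its founder mosaic has {runs} segments from founders",
      sorted(set(founders)))
# Each breakpoint separates two founder segments inherited through the
# parent's two homologs; the mosaic is what the pipeline must reconstruct.
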