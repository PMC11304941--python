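# magicphase

Pedigree-aware phasing and crossover detection for multiparental (MAGIC)
populations, robust to genotyping errors.

Multiparent Advanced Generation Inter-Cross (MAGIC) populations descend
from a panel of homozygous founder lines through a fully recorded
pedigree. That structure allows each individual's diploid SNP genotypes
to be phased deterministically by family trios, every phased allele to
be traced to a grandparental homolog — and therefore every meiotic
crossover (CO) to be located as a transition between grandparental
origins. The practical obstacle is genotyping error (GE): on
high-throughput SNP arrays for complex plant genomes, a single wrong
call can fabricate a spurious haploblock and with it a pair of false
crossovers. `magicphase` addresses this with haploblock filtering by a
minimum number of informative alleles, plus configurable phase
imputation and correction.

The package is aimed at plant-breeding and quantitative-genetics work
(recombination-map construction, CO hotspot analysis, recombination QTL
scans) and is usable both as a Python library and as a command-line
tool on standard PLINK flat files.

## Method

Working upward from the founders (G0, homozygous by assumption):

1. **Trio phasing.** G1 phases follow directly from the founder
   haplotypes. Each later individual is phased per locus against its
   parents' genotypes by Mendelian segregation; loci where phasing is
   impossible are tagged TH (all trio members heterozygous), MD
   (missing data) or ME (Mendelian error).
2. **Grandparental origins.** Each phased allele is compared with the
   transmitting parent's phase: if the parent is heterozygous and
   phased there, the allele's origin is the parent's paternal (P) or
   maternal (M) homolog and the allele is *informative*; alleles from
   homozygous parents are noninformative (`*`), unphased alleles `?`/`!`.
3. **Haploblocks.** Noninformative origins flanked by the same origin
   (or a chromosome border) are imputed, yielding maximal same-origin
   haploblocks. Blocks with fewer than `min` informative alleles are
   discarded and the remaining origins re-imputed, to a fixpoint — this
   is the defence against genotyping error. `min` may vary per
   generation (e.g. `2/5/3` for G2/G3/G4).
4. **Events.** Each adjacent pair of different-origin blocks is one
   recombination event, reported as the closed SNP interval from the
   last locus of the left block to the first locus of the right block.
   With a bp threshold `thr > 0`, events whose shorter flanking block
   spans less than `thr` are classified as gene conversions (GC)
   rather than COs. Origins are also lifted recursively through the
   pedigree to name the founder line behind every allele.
5. **Imputation/correction (optional).** Unresolved phases can be
   imputed from the inferred origins (`imputeTHonly`/`imputeAll`) for
   use in the next generation, and imputations that contradict a
   heterozygous genotype undone or completed
   (`correctFalseHom`/`reImpute`/`correctAll`).

Detection quality is scored against simulated truth with precision
(detected intervals containing a true breakpoint / detected), recall
(/ simulated), F1 = 2PR/(P+R), and resolution = 1/median(candidate SNP
intervals per event); adjusted resolution = precision x resolution. A
built-in simulator generates chain-crossing populations with
Poisson-placed crossovers, recorded breakpoint truth and injectable
genotyping errors, and a calibration routine converts observed
Mendelian-error rates into GE-rate estimates via simulated reference
curves.

## Worked example

```python
from magicphase import (FilterConfig, SimConfig, evaluate_detection,
                        run_pipeline, simulate_population)

pop = simulate_population(SimConfig(seed=1))   # 8 founders, G0-G4, 500 SNPs
res = run_pipeline(pop.pedigree, pop.genotypes, pop.marker_map,
                   FilterConfig(min=1, imp="imputeTHonly", cor="correctFalseHom"))
rep = evaluate_detection(res.events, pop.truth)
print(f"precision={rep.precision:.3f} recall={rep.recall:.3f} f1={rep.f1:.3f}")
```

prints

```
precision=1.000 recall=0.833 f1=0.909
```

every detected interval contains a true breakpoint (no genotyping
errors were simulated, so precision is exactly 1), and 35 of the 42
simulated crossovers are recovered; the missed ones fall outside the
informative marker span or collapse in double-crossover gaps. The
scripts in `examples/` walk through simulation, detection, founder
tracing, the filtering-vs-GE benchmark (where min=3 lifts precision at
a 10% GE rate from ~0.06 to ~0.57 at desk scale) and GE calibration.

The same pipeline runs from the shell:

```sh
magicphase simulate --out sim --seed 1
magicphase phase --ped sim.ped --map sim.map --out run --min 2/5/3 \
    --imp imputeTHonly --cor correctFalseHom
magicphase evaluate --events run.events.tsv --truth sim.truth.tsv
```

Input is a PLINK PED file (pedigree columns + two allele columns per
SNP; 0 = missing, 1 = major, 2 = minor) with a 4-column MAP file
(genetic distances ignored). Outputs are TSV tables of per-homolog
phases, origin strings, and events with founder labels.

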