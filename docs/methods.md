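# Methods

## Model and assumptions

`magicphase` phases multiparental-population SNP genotypes and detects
recombination purely from pedigree structure and Mendelian segregation;
there is no population-genetic model, no LD, and no probabilistic
phasing. The assumptions it relies on:

- **Homozygous founders.** Every G0 individual is an inbred line; a
  heterozygous founder locus raises an error naming the individual and
  marker. This is what makes G1 phases exact and the whole forward
  pass deterministic.
- **Full trios.** An individual is phased only if both parents are
  phased (founders: genotyped). Individuals with a single named,
  genotyped or phased parent are skipped with a warning, as are their
  descendants' broken trios.
- **Biallelic markers** on the 0/1/2 (missing/major/minor) code.
  Half-missing genotypes are promoted to fully missing because the
  segregation logic needs both alleles.
- **Forward-only pipeline.** Parental phases are never revised in the
  light of offspring data; a genotype inconsistent with the parents is
  flagged ME at the offspring locus only.

Phasing failure states are data, not errors: TH (all three trio
members heterozygous — the assignment is genuinely ambiguous), MD
(missing genotype in the trio), ME (no Mendelian-consistent
assignment).

## Origin inference and filtering

For the offspring's paternal homolog (maternal is mirrored), the allele
at a locus is informative iff the father's phase is complete and
heterozygous there; its origin is then P or M according to which
paternal homolog carries the allele. Everything else is noninformative:
`*` (homozygous parent), `?` (TH/MD, or an incompletely phased parent),
`!` (ME). For haploblock construction all noninformative states behave
identically; they differ only in phase-imputation eligibility.

Completion imputes noninformative runs flanked by the same origin on
both sides, and border runs from their single flank. Runs between
different origins stay unassigned and become the recombination
interval. Filtering removes every block with fewer than `min`
informative alleles (imputed loci never count), then re-runs
completion; the sweep repeats to a fixpoint. The fixpoint matters
because removing a block can merge its two same-origin neighbours into
a block whose count must be re-checked; a sweep can also remove two
adjacent blocks, leaving a widened, permanently unassigned gap between
different origins. `min = 1` is the identity. An equivalence test
checks the whole pipeline against an independent brute-force
run-enumeration oracle on exhaustively enumerated micro-families.

Events are reported per homolog, i.e. per meiosis: the paternal
homolog's transitions are crossovers of the father's meiosis. The
interval is closed, `[last locus of left block, first locus of right
block]`, so the true breakpoint lies strictly inside. Classification
with `thr > 0` calls an event a gene conversion when the *shorter*
flanking block spans less than `thr` bp. The published rule names both
inequalities without saying which flank; the minimum is used here
because a conversion tract manifests as one short interior block. This
is a deliberate interpretation and is flagged as such.

Phase imputation fills a TH (or, under `imputeAll`, also MD/ME) locus
with the allele carried by the parent's haplotype of the imputed
origin. `correctFalseHom` undoes pairs of imputations that render a
heterozygous genotype homozygous; `reImpute` fills the second homolog
with the remaining genotype allele when exactly one homolog is known.
One consequence worth stating: under `imputeAll`, an ME locus is
deliberately overwritten with the pedigree-consistent allele, so the
phase no longer reproduces the (erroneous) genotype there. The
consistency checker therefore exempts imputed-over-ME loci by default;
with error-free data the exemption is vacuous and phase/genotype
consistency holds exactly after every stage.

For downstream generations, a parent presents its phase-derived allele
pair wherever both homologs carry alleles, falling back to the
genotype table elsewhere — this is what makes imputed loci usable for
phasing the next generation.

## Simulator

The simulator emulates the analysis conditions rather than any
coalescent history:

- **Founders**: one homozygous haplotype each; per-locus minor-allele
  frequency drawn uniformly from 0.1–0.5, alleles i.i.d. across loci.
  Founder LD is irrelevant to trio phasing, so none is modelled.
- **Pedigree**: chain crossing — neighbouring individuals of each
  generation are crossed — to G4 by default, mirroring the structure
  of real winter-rapeseed MPPs; 8 founders, 1 offspring per cross, all
  generations genotyped.
- **Meiosis**: crossover count ~ Poisson(1.5) per chromosome,
  breakpoints uniform in bp with no interference. The default mean
  brackets the 0.7–1.51 CO/chromosome/meiosis range reported for
  *Brassica napus*. Breakpoints are resampled off exact marker
  coordinates so that a breakpoint always falls strictly between two
  markers (a breakpoint *at* a shared boundary marker could otherwise
  be matched by two adjacent detected intervals at once).
- **Map**: one chromosome of 30 Mb with 500 uniformly placed SNPs by
  default; genetic distance is never used.
- **Errors**: per genotype of the targeted generations (G2–G4 when
  enabled), with the generation's GE rate, one uniformly chosen allele
  is flipped to the other code — so heterozygous calls can become
  homozygous and vice versa. The exact perturbation kernel is a
  choice; conclusions that depend on the GE→ME relationship go through
  the empirical calibration below rather than the kernel.
- **Truth**: breakpoints are recorded per meiosis for non-founder
  parents only. A founder's two homologs are identical, so crossovers
  in a founder's meiosis are invisible in principle and scoring them
  would deflate recall for reasons no detector can address.

What passing tests on these simulations does *not* show: behaviour
under founder LD or residual founder heterozygosity, missing-data
patterns of real arrays (the simulator injects errors, not missing
calls), segregation distortion, or CO interference.

## Metrics

A detected event matches every true breakpoint inside its closed
interval on the same meiosis; an event containing several breakpoints
counts once as matched, while all its breakpoints count as simulated.
Precision = matched/detected, recall = matched/true,
F1 = 2PR/(P+R); zero denominators yield 0 with a `degenerate` flag.
Resolution is 1/median(candidate SNP intervals per detected event),
where the candidate count is `end_idx - start_idx`, i.e. the number of
marker intervals the breakpoint could occupy; adjusted resolution is
precision × resolution. The CO-count map distributes each event's unit
weight evenly over the SNP intervals it spans, so each recombination
gap sums to 1 and the map total equals the event count exactly.

The Mendelian-error rate is offspring-centric: each genotyped trio
contributes one comparison per locus where all three genotypes are
present. Marker QC drops markers whose per-marker ME rate strictly
exceeds 10% (boundary kept).

## GE-from-ME calibration

The GE rate of real data is unobservable; the ME rate is measurable.
`calibrate_ge_from_me` simulates the template population across a GE
grid, measures global ME, and fits ME = a·GE + b by least squares,
exposing the inverse. The relation is only *locally* linear: the
measured ME/GE ratio falls from ~0.77 at GE = 1% to ~0.66 at GE = 10%,
because multiple errors hitting the same trio-locus partially cancel.
The default grid is therefore (1, 2, 3, 4, 6)% — the mid-range of
rates bracketing the ~3% GE typical of real array data — rather than a
span reaching 15%, and the default calibration template doubles the
offspring per cross so each replicate measures ME on ~9×10⁴ trio-loci.
Three replicates per grid point keep sampling noise well below the
fit's systematic residual.

## Numerical and design choices

- Genotype pairs are stored unordered (sorted); PED column order
  carries no phase meaning.
- Loci are 0-based internally; all reported coordinates are marker ids
  and 1-based bp from the MAP file. The optional BED-style export uses
  0-based half-open intervals.
- MAP loci are grouped by chromosome in order of first appearance and
  sorted by bp (a warning is logged if reordering was needed);
  duplicate bp on one chromosome is an error, as phases and origins
  are position-indexed.
- Filtering sweeps remove all below-threshold blocks simultaneously,
  then re-complete; this makes the fixpoint independent of block
  ordering.
- `min` resolution: a scalar applies to every generation; a map must
  cover every phased generation (missing entries are a configuration
  error, not a fallback).
- Event counts are non-increasing in `min` — asserted over randomized
  simulations rather than proved, since removal sweeps interact with
  completion.
- Determinism: all randomness flows through
  `numpy.random.default_rng(seed)`; equal seeds give byte-identical
  PED/MAP/truth files and pipeline outputs.

## Problem sizes

Tests and the acceptance script use 8-founder, G0–G4, 500-SNP
populations (≈30 individuals, 30 scored meioses, ~45 true crossovers
per replicate), with 10–50 replicates per property and 10⁴ meioses for
the Poisson calibration check. These sizes give stable aggregate
metrics while keeping the whole suite fast on a single CPU.

## Known limitations

- Half-sib families (one shared parent) are out of scope; full trios
  are required.
- No probabilistic origin posteriors: a locus is assigned, imputed or
  unassigned, with no confidence measure beyond the informative count
  of its block.
- Gene-conversion classification depends on marker density: a GC tract
  with no informative marker inside is invisible, and `thr` compares
  block *spans*, which single-locus blocks make zero.
- The ME→GE calibration assumes the simulator's error kernel and the
  target population share the GE→ME transfer; grossly non-random
  error modes (e.g. systematic allele dropout) would violate it.
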