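"""Synthetic multiparental populations with known recombination truth.

Founders are homozygous inbred lines with i.i.d. per-locus alleles; the
population follows a chain-crossing scheme (each pair of neighbouring
individuals of one generation is crossed) for a configurable number of
generations, G0 through G4 by default. Each meiosis draws a Poisson
number of crossovers placed uniformly along the chromosome; genotyping
errors are injected as allele flips in chosen generations. The true
breakpoints and founder-of-origin mosaics are recorded for evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ALLELE_MAJOR, ALLELE_MINOR, ALLELE_MISSING
from .plink_io import GenotypeTable, MarkerMap, Pedigree, PedigreeRecord
import pandas as pd

log = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated population.

    mean_co_per_meiosis defaults to 1.5 crossovers per chromosome per
    meiosis, bracketing the 0.7-1.51 range reported for Brassica napus
    chromosomes. ge_rates maps generation index to a per-genotype error
    probability; generations absent from the map (founders and G1 in
    particular) receive no errors.
    """

    n_founders: int = 8
    depth: int = 4  # number of crossed generations beyond G0 (G0..G4)
    offspring_per_cross: int = 1
    n_loci: int = 500
    chrom: str = "1"
    chrom_length: int = 30_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    mean_co_per_meiosis: float = 1.5
    ge_rates: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise SimulationError("need at least 2 founders")
        if self.n_loci < 1:
            raise SimulationError("need at least 1 locus")
        if self.mean_co_per_meiosis <= 0:
            raise SimulationError("mean_co_per_meiosis must be positive")
        for g, r in self.ge_rates.items():
            if not 0.0 <= r <= 1.0:
                raise SimulationError(f"GE rate {r} for generation {g} outside [0,1]")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise SimulationError("maf_range must satisfy 0 <= lo <= hi <= 1")


@dataclass
class SimulationTruth:
    """Ground truth recorded during simulation.

    breakpoints: per meiosis (child id, homolog) the true crossover bp
    positions — recorded only for meioses of non-founder parents, since
    crossovers between a founder's two identical homologs are invisible
    in principle. founder_of_origin: per individual per homolog the true
    founder line at every locus. errors_per_generation: injected
    genotyping-error counts.
    """

    breakpoints: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    founder_of_origin: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    errors_per_generation: dict[int, int] = field(default_factory=dict)

    def founder(self, iid: str, homolog: str) -> np.ndarray:
        pair = self.founder_of_origin[iid]
        return pair[0] if homolog == "paternal" else pair[1]

    @property
    def n_true(self) -> int:
        return sum(len(v) for v in self.breakpoints.values())


@dataclass
class SimulatedPopulation:
    pedigree: Pedigree
    genotypes: GenotypeTable
    marker_map: MarkerMap
    truth: SimulationTruth

    def __iter__(self):
        return iter((self.pedigree, self.genotypes, self.marker_map, self.truth))


def simulate_founders(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one homozygous haplotype per founder: (n_founders, n_loci) alleles.

    The minor-allele frequency of each locus is sampled uniformly from
    config.maf_range; alleles are independent across loci and founders.
    Founders are redrawn (a handful of times) if any two are identical.
    """
    lo, hi = config.maf_range
    for _ in range(20):
        maf = rng.uniform(lo, hi, size=config.n_loci)
        minor = rng.random((config.n_founders, config.n_loci)) < maf[None, :]
        hap = np.where(minor, ALLELE_MINOR, ALLELE_MAJOR).astype(np.int8)
        if len({h.tobytes() for h in hap}) == config.n_founders:
            return hap
    raise SimulationError(
        "could not draw pairwise-distinct founders; increase loci or MAF range"
    )


def meiosis(
    positions: np.ndarray,
    mean_co: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int]]:
    """Draw one gamete's homolog-choice vector and crossover breakpoints.

    The crossover count is Poisson(mean_co); breakpoint bp positions are
    uniform over [first, last) marker positions, resampled off exact
    marker coordinates so a breakpoint always falls strictly between two
    markers. Returns (choice, breakpoints) where choice[i] in {0, 1}
    selects the parental homolog at locus i, alternating from a
    fair-coin starting homolog at each breakpoint.
    """
    start = int(rng.integers(0, 2))
    n_co = int(rng.poisson(mean_co))
    lo, hi = int(positions[0]), int(positions[-1])
    marker_set = set(int(p) for p in positions)
    if hi - lo <= len(marker_set) - 1:  # no bp position strictly between markers
        n_co = 0
    bps: list[int] = []
    for _ in range(n_co):
        b = int(rng.integers(lo, hi))
        while b in marker_set:
            b = int(rng.integers(lo, hi))
        bps.append(b)
    bps.sort()
    crossings = np.searchsorted(np.asarray(bps, dtype=np.int64), positions, side="left")
    choice = (start + crossings) % 2
    return choice.astype(np.int8), bps


def _gamete(
    homolog_pair: np.ndarray, choice: np.ndarray
) -> np.ndarray:
    return np.where(choice == 0, homolog_pair[0], homolog_pair[1])


def _chain_pedigree(config: SimConfig) -> list[PedigreeRecord]:
    records = [
        PedigreeRecord(iid=f"F{i + 1}", father=None, mother=None)
        for i in range(config.n_founders)
    ]
    prev = [r.iid for r in records]
    for g in range(1, config.depth + 1):
        if len(prev) < 2:
            raise SimulationError(
                f"generation {g - 1} has {len(prev)} individuals; cannot chain-cross"
            )
        current = []
        for k, (fa, mo) in enumerate(zip(prev[:-1], prev[1:])):
            for j in range(config.offspring_per_cross):
                suffix = f"_{j + 1}" if config.offspring_per_cross > 1 else ""
                iid = f"G{g}_{k + 1}{suffix}"
                records.append(PedigreeRecord(iid=iid, father=fa, mother=mo))
                current.append(iid)
        prev = current
    return records


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Simulate a chain-crossing population with recombination truth.

    All generations are genotyped. Genotyping errors (config.ge_rates)
    are injected after the true genotypes and truth records are built.
    """
    rng = np.random.default_rng(config.seed)
    positions = np.sort(
        rng.choice(
            np.arange(1, config.chrom_length + 1, dtype=np.int64),
            size=config.n_loci,
            replace=False,
        )
    )
    marker_map = MarkerMap(
        pd.DataFrame(
            {
                "chrom": [config.chrom] * config.n_loci,
                "marker": [f"snp{i + 1}" for i in range(config.n_loci)],
                "bp": positions,
            }
        )
    )

    founder_haps = simulate_founders(config, rng)
    records = _chain_pedigree(config)
    pedigree = Pedigree(records)
    truth = SimulationTruth()

    # per individual: allele homologs (2, n_loci) and founder-label homologs
    haps: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for i, r in enumerate(records):
        if r.father is None:
            haps[r.iid] = np.stack([founder_haps[i], founder_haps[i]])
            labels[r.iid] = np.full((2, config.n_loci), r.iid, dtype=object)
            truth.founder_of_origin[r.iid] = (labels[r.iid][0], labels[r.iid][1])

    for r in records:
        if r.father is None:
            continue
        child_h = []
        child_l = []
        for hom, parent in (("paternal", r.father), ("maternal", r.mother)):
            choice, bps = meiosis(positions, config.mean_co_per_meiosis, rng)
            child_h.append(_gamete(haps[parent], choice))
            child_l.append(_gamete(labels[parent], choice))
            if not pedigree.is_founder(parent):
                truth.breakpoints[(r.iid, hom)] = bps
        haps[r.iid] = np.stack(child_h)
        labels[r.iid] = np.stack(child_l)
        truth.founder_of_origin[r.iid] = (labels[r.iid][0], labels[r.iid][1])

    alleles = np.stack(
        [np.sort(np.stack([haps[r.iid][0], haps[r.iid][1]], axis=1), axis=1) for r in records]
    ).astype(np.int8)
    genotypes = GenotypeTable([r.iid for r in records], marker_map.markers, alleles)

    if config.ge_rates:
        genotypes, counts = inject_errors(genotypes, pedigree, config.ge_rates, rng)
        truth.errors_per_generation = counts
    else:
        truth.errors_per_generation = {}
    return SimulatedPopulation(pedigree, genotypes, marker_map, truth)


def inject_errors(
    genotypes: GenotypeTable,
    pedigree: Pedigree,
    ge_rates: dict[int, float],
    rng: np.random.Generator,
) -> tuple[GenotypeTable, dict[int, int]]:
    """Perturb genotypes of targeted generations with allele flips.

    Independently per individual per locus, with the generation's
    probability, one of the two alleles (chosen uniformly) is flipped to
    the other allele code, so heterozygous calls can become homozygous
    and vice versa. Missing genotypes are never perturbed. Returns the
    perturbed table and per-generation error counts.
    """
    for g, r in ge_rates.items():
        if not 0.0 <= r <= 1.0:
            raise SimulationError(f"GE rate {r} for generation {g} outside [0,1]")
    out = genotypes.copy()
    counts: dict[int, int] = {}
    for row, iid in enumerate(out.individuals):
        gen = pedigree.generation[iid]
        rate = ge_rates.get(gen, 0.0)
        if rate == 0.0:
            continue
        pair = out.alleles[row]
        nonmissing = (pair != ALLELE_MISSING).all(axis=1)
        hit = (rng.random(len(pair)) < rate) & nonmissing
        which = rng.integers(0, 2, size=len(pair))
        idx = np.flatnonzero(hit)
        flipped = pair.copy()
        flipped[idx, which[idx]] = np.where(
            flipped[idx, which[idx]] == ALLELE_MAJOR, ALLELE_MINOR, ALLELE_MAJOR
        )
        out.alleles[row] = np.sort(flipped, axis=1)
        counts[gen] = counts.get(gen, 0) + len(idx)
    return out, counts


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def _rle(arr: np.ndarray) -> str:
    runs = []
    i = 0
    n = len(arr)
    while i < n:
        j = i
        while j + 1 < n and arr[j + 1] == arr[i]:
            j += 1
        runs.append(f"{arr[i] if arr[i] is not None else '.'}:{j - i + 1}")
        i = j + 1
    return ",".join(runs)


def _unrle(s: str) -> np.ndarray:
    out = []
    for run in s.split(","):
        val, count = run.rsplit(":", 1)
        out.extend([None if val == "." else val] * int(count))
    return np.array(out, dtype=object)


def write_truth(truth: SimulationTruth, pedigree: Pedigree, path) -> None:
    """TSV: one row per (individual, homolog) with breakpoints and founder RLE."""
    with open(path, "w") as fh:
        fh.write("individual\thomolog\tbreakpoints\tfounder_rle\n")
        for iid, (pat, mat) in truth.founder_of_origin.items():
            for hom, arr in (("paternal", pat), ("maternal", mat)):
                key = (iid, hom)
                bps = truth.breakpoints.get(key)
                bp_str = ",".join(str(b) for b in bps) if bps else "."
                if bps is None:
                    bp_str = "NA"  # meiosis not scored (founder parent or founder)
                fh.write(f"{iid}\t{hom}\t{bp_str}\t{_rle(arr)}\n")


def read_truth(path) -> SimulationTruth:
    truth = SimulationTruth()
    mosaics: dict[str, dict[str, np.ndarray]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            iid, hom, bp_str, rle = line.rstrip("\n").split("\t")
            if bp_str not in ("NA",):
                truth.breakpoints[(iid, hom)] = (
                    [] if bp_str == "." else [int(b) for b in bp_str.split(",")]
                )
            mosaics.setdefault(iid, {})[hom] = _unrle(rle)
    for iid, homs in mosaics.items():
        truth.founder_of_origin[iid] = (homs["paternal"], homs["maternal"])
    return truth
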