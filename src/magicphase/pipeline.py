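"""End-to-end pipeline: phase generations, infer origins, filter, detect events.

Processing runs from the founders upward. Children of two founders are
phased directly; every later individual is phased by trio against its
parents' effective genotypes, its grandparental origin mosaic is built
and filtered, unresolved phases are optionally imputed and corrected,
and origin transitions become recombination events. The corrected
phases feed the next generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .constants import CO, GC, OR_M, OR_P
from .events import (
    FounderAssignment,
    RecombinationEvent,
    detect_events,
    trace_founders,
)
from .origins import (
    FilterConfig,
    OriginMosaic,
    assign_origins,
    complete_haploblocks,
    filter_haploblocks,
    resolve_min,
)
from .phasing import (
    PhasePair,
    check_phase_consistency,
    correct_phases,
    effective_genotype,
    founder_phase,
    impute_phases,
    phase_g1,
    phase_trio,
)
from .plink_io import GenotypeTable, MarkerMap, Pedigree

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    phases: dict[str, PhasePair]
    mosaics: dict[str, OriginMosaic]
    events: list[RecombinationEvent]
    founders: dict[str, FounderAssignment]
    stats: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def run_pipeline(
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    marker_map: MarkerMap,
    config: FilterConfig | None = None,
    validate: bool = False,
) -> PipelineResult:
    """Run phasing, origin inference, filtering and event detection.

    Individuals with an unphased or ungenotyped parent are skipped with
    a warning (full trios are required). ``validate`` re-checks phase/
    genotype consistency after each individual's correction stage.
    """
    config = config or FilterConfig()
    if genotypes.n_loci != marker_map.n_loci:
        raise ValueError("genotype table and marker map disagree on locus count")
    slices = marker_map.chrom_slices()
    markers = marker_map.markers

    by_gen = pedigree.by_generation()
    if pedigree.max_generation == 0:
        log.warning("pedigree contains only founders; nothing to phase")
        return PipelineResult({}, {}, [], {}, pd.DataFrame(), [])

    phases: dict[str, PhasePair] = {}
    mosaics: dict[str, OriginMosaic] = {}
    events: list[RecombinationEvent] = []
    skipped: list[str] = []
    stat_rows = []

    # Founders: trivial homozygous phases (asserts the G0 assumption).
    for iid in by_gen.get(0, []):
        if iid in genotypes:
            phases[iid] = founder_phase(genotypes.genotype(iid), iid, markers)

    for gen in sorted(g for g in by_gen if g >= 1):
        gen_events = 0
        gen_phased = 0
        info_num = info_den = 0
        for iid in by_gen[gen]:
            father, mother = pedigree.parents_of(iid)
            if father is None or mother is None:
                log.warning("%s has a single named parent; skipped", iid)
                skipped.append(iid)
                continue
            if father not in phases or mother not in phases:
                log.warning("%s has an unphased/ungenotyped parent; skipped", iid)
                skipped.append(iid)
                continue
            both_founders = pedigree.is_founder(father) and pedigree.is_founder(mother)
            if both_founders:
                phases[iid] = phase_g1(
                    genotypes.genotype(father),
                    genotypes.genotype(mother),
                    father,
                    mother,
                    markers,
                )
                gen_phased += 1
                continue
            if iid not in genotypes:
                log.warning("%s is not genotyped; skipped", iid)
                skipped.append(iid)
                continue
            off_gt = genotypes.genotype(iid)
            eff_fa = effective_genotype(
                phases[father],
                genotypes.genotype(father) if father in genotypes else None,
            )
            eff_mo = effective_genotype(
                phases[mother],
                genotypes.genotype(mother) if mother in genotypes else None,
            )
            ph = phase_trio(eff_fa, eff_mo, off_gt)
            mosaic = assign_origins(ph, phases[father], phases[mother])
            mosaic = complete_haploblocks(mosaic, slices)
            mosaic = filter_haploblocks(mosaic, resolve_min(config, gen), slices)
            ph = impute_phases(ph, mosaic, phases[father], phases[mother], config.imp)
            ph = correct_phases(ph, off_gt, config.cor)
            if validate:
                check_phase_consistency(ph, off_gt, iid)
            phases[iid] = ph
            mosaics[iid] = mosaic
            ind_events = detect_events(mosaic, marker_map, iid, config.thr)
            events.extend(ind_events)
            gen_events += len(ind_events)
            gen_phased += 1
            for hom in ("paternal", "maternal"):
                info_num += int(mosaic.informative(hom).sum())
                info_den += mosaic.n_loci
        stat_rows.append(
            {
                "generation": gen,
                "n_individuals": len(by_gen[gen]),
                "n_phased": gen_phased,
                "frac_informative": (info_num / info_den) if info_den else float("nan"),
                "n_events": gen_events,
            }
        )
        log.info(
            "G%d: phased %d/%d individuals, %d events",
            gen,
            gen_phased,
            len(by_gen[gen]),
            gen_events,
        )

    founders = trace_founders(mosaics, pedigree, marker_map.n_loci)
    stats = pd.DataFrame(stat_rows)
    return PipelineResult(phases, mosaics, events, founders, stats, skipped)


def phase_population(
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    marker_map: MarkerMap,
    config: FilterConfig | None = None,
    validate: bool = False,
) -> PipelineResult:
    """Alias of run_pipeline (the population-level phasing entry point)."""
    return run_pipeline(pedigree, genotypes, marker_map, config, validate)
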