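"""Recombination-event detection, CO/GC classification and founder tracing.

A recombination event is a transition between grandparental origins on
one homolog: the recombination interval runs from the last locus of the
left haploblock to the first locus of the right haploblock, so the true
breakpoint lies within the reported coordinates. The paternal homolog's
events belong to the father's meiosis, the maternal to the mother's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import CO, GC, HOMOLOGS, OR_M, OR_P
from .origins import Haploblock, OriginMosaic, haploblocks
from .plink_io import MarkerMap, Pedigree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecombinationEvent:
    """One origin transition within one meiosis."""

    individual: str
    homolog: str  # "paternal" => father's meiosis, "maternal" => mother's
    chrom: str
    left_origin: int
    right_origin: int
    start_idx: int  # last locus index of the left block (global)
    end_idx: int    # first locus index of the right block (global)
    start_bp: int
    end_bp: int
    start_marker: str
    end_marker: str
    klass: str = CO

    @property
    def n_intervals(self) -> int:
        """Candidate SNP intervals for the breakpoint."""
        return self.end_idx - self.start_idx

    @property
    def meiosis(self) -> tuple[str, str]:
        return (self.individual, self.homolog)


@dataclass
class FounderAssignment:
    """Per-homolog, per-locus founder line of origin (None if untraceable)."""

    pat_founder: np.ndarray  # object array of founder ids / None
    mat_founder: np.ndarray

    def founder(self, homolog: str, locus: int):
        arr = self.pat_founder if homolog == "paternal" else self.mat_founder
        return arr[locus]

    def homolog(self, homolog: str) -> np.ndarray:
        return self.pat_founder if homolog == "paternal" else self.mat_founder


def classify_event(
    event: RecombinationEvent,
    left_block: Haploblock,
    right_block: Haploblock,
    marker_map: MarkerMap,
    thr: int,
) -> str:
    """Classify an origin transition as crossover or gene conversion.

    With thr = 0 every event is a CO. Otherwise the event is a gene
    conversion when the shorter of the two flanking haploblocks spans
    less than thr bp — a conversion tract manifests as one short interior
    block, so the minimum is the discriminating length.
    """
    if thr <= 0:
        return CO
    pos = marker_map.positions
    left_len = int(pos[left_block.end] - pos[left_block.start])
    right_len = int(pos[right_block.end] - pos[right_block.start])
    return GC if min(left_len, right_len) < thr else CO


def detect_events(
    mosaic: OriginMosaic,
    marker_map: MarkerMap,
    individual: str,
    thr: int = 0,
) -> list[RecombinationEvent]:
    """One event per adjacent haploblock pair with different origins.

    The mosaic should already be completed and filtered; any unassigned
    gap between the flanking blocks is captured inside the interval.
    """
    pos = marker_map.positions
    markers = marker_map.markers
    slices = marker_map.chrom_slices()
    out: list[RecombinationEvent] = []
    for hom in HOMOLOGS:
        for chrom, lo, hi in slices:
            blocks = [
                b for b in haploblocks(mosaic, [(chrom, lo, hi)]) if b.homolog == hom
            ]
            for left, right in zip(blocks[:-1], blocks[1:]):
                ev = RecombinationEvent(
                    individual=individual,
                    homolog=hom,
                    chrom=chrom,
                    left_origin=left.origin,
                    right_origin=right.origin,
                    start_idx=left.end,
                    end_idx=right.start,
                    start_bp=int(pos[left.end]),
                    end_bp=int(pos[right.start]),
                    start_marker=markers[left.end],
                    end_marker=markers[right.start],
                )
                klass = classify_event(ev, left, right, marker_map, thr)
                if klass != ev.klass:
                    ev = RecombinationEvent(**{**ev.__dict__, "klass": klass})
                out.append(ev)
    return out


def write_bed(events: list[RecombinationEvent], path) -> None:
    """Export event intervals as BED (0-based half-open) for genome browsers."""
    with open(path, "w") as fh:
        for ev in events:
            name = f"{ev.individual}:{ev.homolog}:{ev.klass}"
            fh.write(f"{ev.chrom}\t{ev.start_bp - 1}\t{ev.end_bp}\t{name}\n")


def trace_founders(
    all_mosaics: dict[str, OriginMosaic],
    pedigree: Pedigree,
    n_loci: int | None = None,
) -> dict[str, FounderAssignment]:
    """Lift grandparental origins recursively to founder lines.

    A G1 individual's paternal/maternal homologs are its founder parents'
    haplotypes themselves; deeper individuals map origin P/M at a locus
    to the corresponding parental homolog's founder at that locus. Any
    unassigned origin along the chain leaves the locus untraceable.
    """
    if n_loci is None:
        for m in all_mosaics.values():
            n_loci = m.n_loci
            break
    if n_loci is None:
        return {}

    out: dict[str, FounderAssignment] = {}
    n_gap = 0
    by_gen = pedigree.by_generation()
    for gen in sorted(g for g in by_gen if g >= 1):
        for iid in by_gen[gen]:
            father, mother = pedigree.parents_of(iid)
            if father is None or mother is None:
                continue
            if pedigree.is_founder(father) and pedigree.is_founder(mother):
                out[iid] = FounderAssignment(
                    np.full(n_loci, father, dtype=object),
                    np.full(n_loci, mother, dtype=object),
                )
                continue
            if iid not in all_mosaics:
                continue
            mosaic = all_mosaics[iid]
            homs = []
            for hom, parent in (("paternal", father), ("maternal", mother)):
                arr = np.full(n_loci, None, dtype=object)
                if pedigree.is_founder(parent):
                    # a founder's gamete is its own haplotype everywhere
                    arr[:] = parent
                    homs.append(arr)
                    continue
                pa = out.get(parent)
                if pa is None:
                    n_gap += n_loci
                else:
                    origin = mosaic.origin(hom)
                    for code, src in (
                        (OR_P, pa.pat_founder),
                        (OR_M, pa.mat_founder),
                    ):
                        m = origin == code
                        arr[m] = src[m]
                    n_gap += int((arr == None).sum())  # noqa: E711
                homs.append(arr)
            out[iid] = FounderAssignment(homs[0], homs[1])
    if n_gap:
        log.debug("%d homolog-loci could not be traced to a founder", n_gap)
    return out
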