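"""Grandparental haplotype origin inference and haploblock filtering.

An offspring's phased allele is assigned origin P (grandpaternal) or M
(grandmaternal) when the transmitting parent is heterozygous and phased
at that locus — such alleles are *informative*. Noninformative origins
between same-origin informative alleles (or at a chromosome border) are
imputed, forming haploblocks; blocks with fewer than ``min`` informative
alleles are discarded and the remaining origins re-imputed, which is the
pipeline's defence against genotyping error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    COR_MODES,
    HOMOLOGS,
    IMP_MODES,
    OR_BANG,
    OR_M,
    OR_NONE,
    OR_P,
    OR_Q,
    ST_IMPUTED,
    ST_MD,
    ST_ME,
    ST_RESOLVED,
    ST_TH,
)
from .phasing import PhasePair

log = logging.getLogger(__name__)

ASSIGNED = (OR_P, OR_M)


class ConfigError(ValueError):
    """Invalid filtering/imputation configuration."""


@dataclass
class OriginMosaic:
    """Per-homolog, per-locus grandparental origin states for one individual.

    The informative flag marks origins assigned directly from a
    heterozygous, phased parent; imputed origins never set it.
    """

    pat_origin: np.ndarray
    mat_origin: np.ndarray
    pat_informative: np.ndarray
    mat_informative: np.ndarray

    @property
    def n_loci(self) -> int:
        return len(self.pat_origin)

    def origin(self, homolog: str) -> np.ndarray:
        return self.pat_origin if homolog == "paternal" else self.mat_origin

    def informative(self, homolog: str) -> np.ndarray:
        return self.pat_informative if homolog == "paternal" else self.mat_informative

    def copy(self) -> "OriginMosaic":
        return OriginMosaic(
            self.pat_origin.copy(),
            self.mat_origin.copy(),
            self.pat_informative.copy(),
            self.mat_informative.copy(),
        )


@dataclass(frozen=True)
class Haploblock:
    """Maximal run of loci on one homolog sharing an assigned origin."""

    homolog: str
    origin: int
    start: int  # inclusive locus index
    end: int    # inclusive locus index
    informative_count: int


@dataclass
class FilterConfig:
    """Pipeline options: min informative alleles, imputation, correction, thr.

    ``min`` may be a scalar applied to every generation or a map from
    generation index to threshold. ``thr`` (bp) separates gene conversions
    from crossovers; 0 disables the distinction.
    """

    min: int | dict = 1
    imp: str = "imputeNot"
    cor: str = "correctNot"
    thr: int = 0

    def __post_init__(self) -> None:
        if self.imp not in IMP_MODES:
            raise ConfigError(f"imp must be one of {IMP_MODES}, got {self.imp!r}")
        if self.cor not in COR_MODES:
            raise ConfigError(f"cor must be one of {COR_MODES}, got {self.cor!r}")
        if self.imp == "imputeNot" and self.cor != "correctNot":
            raise ConfigError("imp=imputeNot forces cor=correctNot")
        if self.imp == "imputeAll" and self.cor == "correctNot":
            log.warning("imputeAll with correctNot is not recommended")
        mins = self.min.values() if isinstance(self.min, dict) else [self.min]
        if any(int(m) < 1 for m in mins):
            raise ConfigError("min must be >= 1")
        if int(self.thr) < 0:
            raise ConfigError("thr must be >= 0")


def resolve_min(config: FilterConfig, generation: int) -> int:
    """Per-generation min threshold; a scalar applies to all generations."""
    if isinstance(config.min, dict):
        if generation not in config.min:
            raise ConfigError(f"no min threshold configured for generation {generation}")
        return int(config.min[generation])
    return int(config.min)


def _assign_homolog(
    off_allele: np.ndarray,
    off_state: np.ndarray,
    parent: PhasePair,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(off_allele)
    origin = np.full(n, OR_NONE, np.int8)
    informative = np.zeros(n, bool)

    origin[np.isin(off_state, (ST_TH, ST_MD))] = OR_Q
    origin[off_state == ST_ME] = OR_BANG

    phased = off_allele > 0
    p, m = parent.pat_allele, parent.mat_allele
    complete = (p > 0) & (m > 0)
    het = complete & (p != m)

    is_p = phased & het & (off_allele == p)
    is_m = phased & het & (off_allele == m)
    origin[is_p] = OR_P
    origin[is_m] = OR_M
    informative[is_p | is_m] = True
    # resolved offspring allele matching neither parental homolog
    origin[phased & het & ~is_p & ~is_m] = OR_BANG
    # parent homozygous: noninformative; parent phase incomplete: missing info
    origin[phased & ~complete] = OR_Q
    # (phased & complete & ~het) keeps OR_NONE: homozygous parent
    return origin, informative


def assign_origins(
    offspring_phase: PhasePair,
    father_phase: PhasePair,
    mother_phase: PhasePair,
) -> OriginMosaic:
    """Compare an offspring's phase with its parents' to assign origins.

    The paternal homolog is read against the father's phase, the maternal
    against the mother's. Alleles from homozygous parents are
    noninformative (*); unphased offspring alleles are ? (TH/MD) or !
    (ME); an allele matching neither homolog of a fully phased
    heterozygous parent is flagged !.
    """
    po, pi = _assign_homolog(
        offspring_phase.pat_allele, offspring_phase.pat_state, father_phase
    )
    mo, mi = _assign_homolog(
        offspring_phase.mat_allele, offspring_phase.mat_state, mother_phase
    )
    return OriginMosaic(po, mo, pi, mi)


def _complete_segment(origin: np.ndarray) -> np.ndarray:
    """Impute noninformative origins between same-origin flanks or borders."""
    out = origin.copy()
    assigned = np.flatnonzero(np.isin(out, ASSIGNED))
    if assigned.size == 0:
        return out
    first, last = assigned[0], assigned[-1]
    out[:first] = out[first]
    out[last + 1:] = out[last]
    for a, b in zip(assigned[:-1], assigned[1:]):
        if b > a + 1 and out[a] == out[b]:
            out[a + 1: b] = out[a]
    return out


def _segment_blocks(
    origin: np.ndarray, informative: np.ndarray, homolog: str, offset: int = 0
) -> list[Haploblock]:
    blocks: list[Haploblock] = []
    n = len(origin)
    i = 0
    while i < n:
        if origin[i] in ASSIGNED:
            j = i
            while j + 1 < n and origin[j + 1] == origin[i]:
                j += 1
            blocks.append(
                Haploblock(
                    homolog,
                    int(origin[i]),
                    offset + i,
                    offset + j,
                    int(informative[i: j + 1].sum()),
                )
            )
            i = j + 1
        else:
            i += 1
    return blocks


def haploblocks(mosaic: OriginMosaic, chrom_slices=None) -> list[Haploblock]:
    """All haploblocks of a (completed) mosaic, per homolog per chromosome."""
    if chrom_slices is None:
        chrom_slices = [("1", 0, mosaic.n_loci)]
    out: list[Haploblock] = []
    for hom in HOMOLOGS:
        origin = mosaic.origin(hom)
        info = mosaic.informative(hom)
        for _, lo, hi in chrom_slices:
            out.extend(_segment_blocks(origin[lo:hi], info[lo:hi], hom, lo))
    return out


def complete_haploblocks(mosaic: OriginMosaic, chrom_slices=None) -> OriginMosaic:
    """Impute noninformative origins flanked by a single origin or a border.

    Runs between blocks of *different* origins stay unassigned — they
    become the recombination interval. A homolog (chromosome segment)
    with no informative origin at all is left unassigned.
    """
    if chrom_slices is None:
        chrom_slices = [("1", 0, mosaic.n_loci)]
    out = mosaic.copy()
    for hom in HOMOLOGS:
        origin = out.origin(hom)
        for chrom, lo, hi in chrom_slices:
            seg = _complete_segment(origin[lo:hi])
            if not np.isin(seg, ASSIGNED).any():
                log.debug("homolog %s chromosome %s has no informative origin", hom, chrom)
            origin[lo:hi] = seg
    return out


def filter_haploblocks(
    mosaic: OriginMosaic, min_informative: int, chrom_slices=None
) -> OriginMosaic:
    """Discard haploblocks with fewer than ``min_informative`` informative alleles.

    Each sweep resets every below-threshold block to noninformative
    (clearing informative flags), then re-runs haploblock completion;
    sweeps repeat until no block falls below the threshold, so cascades
    from merged neighbours are handled. ``min_informative = 1`` is the
    identity on a completed mosaic.
    """
    if min_informative < 1:
        raise ConfigError("min must be >= 1")
    out = complete_haploblocks(mosaic, chrom_slices)
    if min_informative == 1:
        return out
    while True:
        removed = False
        for block in haploblocks(out, chrom_slices):
            if block.informative_count < min_informative:
                origin = out.origin(block.homolog)
                info = out.informative(block.homolog)
                origin[block.start: block.end + 1] = OR_NONE
                info[block.start: block.end + 1] = False
                removed = True
        if not removed:
            return out
        out = complete_haploblocks(out, chrom_slices)
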