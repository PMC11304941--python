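"""Trio-based Mendelian phasing of diploid SNP genotypes.

The pipeline works generation by generation: children of two homozygous
founders are phased directly; later generations are phased against their
parents' genotypes with Mendelian segregation rules. Loci that cannot be
phased are tagged TH (all trio members heterozygous), MD (missing data)
or ME (Mendelian error) and can later be imputed from inferred haplotype
origins and corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import (
    ALLELE_MISSING,
    OR_M,
    OR_P,
    ST_IMPUTED,
    ST_MD,
    ST_ME,
    ST_RESOLVED,
    ST_TH,
)

log = logging.getLogger(__name__)


class FounderHeterozygosityError(ValueError):
    """A founder violated the homozygosity assumption."""


class PhaseConsistencyError(AssertionError):
    """A resolved phase disagreed with the underlying genotype."""


@dataclass
class PhasePair:
    """Two ordered allele sequences (paternal, maternal) for one individual.

    ``*_allele`` holds codes from {1, 2} with 0 meaning no allele carried;
    ``*_state`` is RESOLVED/TH/MD/ME/IMPUTED per locus. ``cause`` records
    the original trio-phasing failure state (TH/MD/ME, else RESOLVED) so
    that undone imputations can fall back to it.
    """

    pat_allele: np.ndarray
    mat_allele: np.ndarray
    pat_state: np.ndarray
    mat_state: np.ndarray
    cause: np.ndarray

    @property
    def n_loci(self) -> int:
        return len(self.pat_allele)

    def allele(self, homolog: str) -> np.ndarray:
        return self.pat_allele if homolog == "paternal" else self.mat_allele

    def state(self, homolog: str) -> np.ndarray:
        return self.pat_state if homolog == "paternal" else self.mat_state

    def has_allele(self, homolog: str) -> np.ndarray:
        return self.allele(homolog) > 0

    def copy(self) -> "PhasePair":
        return PhasePair(
            self.pat_allele.copy(),
            self.mat_allele.copy(),
            self.pat_state.copy(),
            self.mat_state.copy(),
            self.cause.copy(),
        )


def _empty_phase(n: int) -> PhasePair:
    return PhasePair(
        np.zeros(n, np.int8),
        np.zeros(n, np.int8),
        np.zeros(n, np.int8),
        np.zeros(n, np.int8),
        np.zeros(n, np.int8),
    )


def founder_phase(genotype: np.ndarray, iid: str = "?", markers=None) -> PhasePair:
    """Trivial phase of a homozygous founder: both homologs carry its allele.

    Raises FounderHeterozygosityError on any heterozygous locus.
    """
    g = np.asarray(genotype)
    miss = (g == ALLELE_MISSING).any(axis=1)
    het = ~miss & (g[:, 0] != g[:, 1])
    if het.any():
        i = int(np.flatnonzero(het)[0])
        marker = markers[i] if markers is not None else f"locus {i}"
        raise FounderHeterozygosityError(
            f"founder {iid!r} is heterozygous at {marker}"
        )
    ph = _empty_phase(len(g))
    ph.pat_allele[~miss] = g[~miss, 0]
    ph.mat_allele[~miss] = g[~miss, 0]
    ph.pat_state[miss] = ST_MD
    ph.mat_state[miss] = ST_MD
    ph.cause[miss] = ST_MD
    return ph


def phase_g1(
    father_genotype: np.ndarray,
    mother_genotype: np.ndarray,
    father_id: str = "father",
    mother_id: str = "mother",
    markers=None,
) -> PhasePair:
    """Phase a child of two homozygous founders directly.

    The paternal homolog carries the father's allele and the maternal the
    mother's at every locus where both founders are genotyped; a missing
    founder genotype yields MD.
    """
    fa = founder_phase(np.asarray(father_genotype), father_id, markers)
    mo = founder_phase(np.asarray(mother_genotype), mother_id, markers)
    n = fa.n_loci
    ph = _empty_phase(n)
    f_ok = fa.pat_allele > 0
    m_ok = mo.pat_allele > 0
    both = f_ok & m_ok
    ph.pat_allele[both] = fa.pat_allele[both]
    ph.mat_allele[both] = mo.pat_allele[both]
    ph.pat_state[~both] = ST_MD
    ph.mat_state[~both] = ST_MD
    ph.cause[~both] = ST_MD
    return ph


def _carries(genotype: np.ndarray, allele: np.ndarray) -> np.ndarray:
    return (genotype[:, 0] == allele) | (genotype[:, 1] == allele)


def phase_trio(
    father_genotype: np.ndarray,
    mother_genotype: np.ndarray,
    offspring_genotype: np.ndarray,
) -> PhasePair:
    """Phase one offspring against its parents' genotypes.

    Per locus: a homozygous offspring a/a is phased (a, a) if both parents
    can transmit a, else ME; a heterozygous offspring a/b is phased if
    exactly one assignment of {a, b} to (father, mother) is Mendelian-
    consistent; both assignments consistent means all three are
    heterozygous (TH); none means ME; any missing genotype yields MD.
    """
    fa = np.asarray(father_genotype)
    mo = np.asarray(mother_genotype)
    of = np.asarray(offspring_genotype)
    n = len(of)
    ph = _empty_phase(n)

    miss = (
        (fa == ALLELE_MISSING).any(axis=1)
        | (mo == ALLELE_MISSING).any(axis=1)
        | (of == ALLELE_MISSING).any(axis=1)
    )
    o1, o2 = of[:, 0], of[:, 1]
    hom = ~miss & (o1 == o2)
    het = ~miss & (o1 != o2)

    hom_ok = hom & _carries(fa, o1) & _carries(mo, o1)
    # father transmits o1 / mother o2, or the reverse
    a1 = het & _carries(fa, o1) & _carries(mo, o2)
    a2 = het & _carries(fa, o2) & _carries(mo, o1)
    th = a1 & a2
    only1 = a1 & ~a2
    only2 = a2 & ~a1
    me = (hom & ~hom_ok) | (het & ~a1 & ~a2)

    ph.pat_allele[hom_ok] = o1[hom_ok]
    ph.mat_allele[hom_ok] = o1[hom_ok]
    ph.pat_allele[only1] = o1[only1]
    ph.mat_allele[only1] = o2[only1]
    ph.pat_allele[only2] = o2[only2]
    ph.mat_allele[only2] = o1[only2]

    for mask, st in ((th, ST_TH), (miss, ST_MD), (me, ST_ME)):
        ph.pat_state[mask] = st
        ph.mat_state[mask] = st
        ph.cause[mask] = st
    return ph


def effective_genotype(phase: PhasePair, genotype: np.ndarray | None) -> np.ndarray:
    """Allele pairs a parent presents to its offspring's trio phasing.

    Wherever both homologs carry an allele (resolved or imputed) the
    phase-derived pair is used — this is what lets imputed loci serve
    later generations; elsewhere the genotype-table value (missing if the
    parent is ungenotyped).
    """
    n = phase.n_loci
    if genotype is None:
        out = np.zeros((n, 2), np.int8)
    else:
        out = np.asarray(genotype).copy()
    both = (phase.pat_allele > 0) & (phase.mat_allele > 0)
    pair = np.stack([phase.pat_allele, phase.mat_allele], axis=1)
    out[both] = np.sort(pair[both], axis=1)
    return out


def impute_phases(
    phase: PhasePair,
    mosaic,
    father_phase: PhasePair,
    mother_phase: PhasePair,
    mode: str,
) -> PhasePair:
    """Fill unresolved phases from inferred haplotype origins.

    imputeNot: unchanged. imputeTHonly: only TH loci whose origin was
    imputed receive the allele carried by the parent's haplotype of that
    origin. imputeAll: TH, MD and ME loci alike. Loci whose origin is
    still unassigned, or whose source parental allele is itself missing,
    are left unchanged.
    """
    if mode == "imputeNot":
        return phase.copy()
    if mode == "imputeTHonly":
        states = (ST_TH,)
    elif mode == "imputeAll":
        states = (ST_TH, ST_MD, ST_ME)
    else:
        raise ValueError(f"unknown imp mode {mode!r}")

    out = phase.copy()
    for hom, parent in (("paternal", father_phase), ("maternal", mother_phase)):
        st = out.state(hom)
        al = out.allele(hom)
        org = mosaic.origin(hom)
        target = np.isin(st, states)
        for origin_code, src in ((OR_P, parent.pat_allele), (OR_M, parent.mat_allele)):
            m = target & (org == origin_code) & (src > 0)
            al[m] = src[m]
            st[m] = ST_IMPUTED
    return out


def correct_phases(phase: PhasePair, genotype: np.ndarray, mode: str) -> PhasePair:
    """Post-imputation correction at heterozygous-genotype loci.

    correctFalseHom undoes pairs of imputations that made a heterozygous
    genotype look homozygous; reImpute fills the second homolog with the
    remaining genotype allele when exactly one homolog is known;
    correctAll chains both. correctNot is the identity.
    """
    if mode == "correctNot":
        return phase.copy()
    if mode not in ("correctFalseHom", "reImpute", "correctAll"):
        raise ValueError(f"unknown cor mode {mode!r}")

    out = phase.copy()
    g = np.asarray(genotype)
    het = (g[:, 0] != g[:, 1]) & (g != ALLELE_MISSING).all(axis=1)

    if mode in ("correctFalseHom", "correctAll"):
        false_hom = (
            het
            & (out.pat_state == ST_IMPUTED)
            & (out.mat_state == ST_IMPUTED)
            & (out.pat_allele == out.mat_allele)
        )
        for al, st in ((out.pat_allele, out.pat_state), (out.mat_allele, out.mat_state)):
            al[false_hom] = 0
            st[false_hom] = out.cause[false_hom]

    if mode in ("reImpute", "correctAll"):
        for known_al, other_al, other_st in (
            (out.pat_allele, out.mat_allele, out.mat_state),
            (out.mat_allele, out.pat_allele, out.pat_state),
        ):
            one_side = het & (known_al > 0) & (other_al == 0)
            # remaining genotype allele given the known homolog's allele
            rem = np.where(known_al == g[:, 0], g[:, 1], g[:, 0]).astype(np.int8)
            valid = one_side & ((known_al == g[:, 0]) | (known_al == g[:, 1]))
            other_al[valid] = rem[valid]
            other_st[valid] = ST_IMPUTED
    return out


def check_phase_consistency(
    phase: PhasePair,
    genotype: np.ndarray,
    iid: str = "?",
    ignore_imputed_me: bool = True,
) -> None:
    """Assert that fully phased loci reproduce the unphased genotype.

    Loci imputed over a Mendelian-error call are exempt by default: there
    the imputation deliberately overrides a genotype already flagged as
    inconsistent with the pedigree.
    """
    g = np.asarray(genotype)
    both = (phase.pat_allele > 0) & (phase.mat_allele > 0)
    nonmiss = (g != ALLELE_MISSING).all(axis=1)
    checked = both & nonmiss
    if ignore_imputed_me:
        imputed_me = (phase.cause == ST_ME) & (
            (phase.pat_state == ST_IMPUTED) | (phase.mat_state == ST_IMPUTED)
        )
        checked &= ~imputed_me
    pair = np.sort(np.stack([phase.pat_allele, phase.mat_allele], axis=1), axis=1)
    bad = checked & ~(pair == g).all(axis=1)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise PhaseConsistencyError(
            f"individual {iid!r} locus {i}: phase {tuple(pair[i])} vs "
            f"genotype {tuple(g[i])}"
        )


def phase_population(pedigree, genotypes, marker_map, config, validate=False):
    """Run the full per-generation pipeline; see magicphase.pipeline."""
    from .pipeline import run_pipeline

    return run_pipeline(pedigree, genotypes, marker_map, config, validate=validate)
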