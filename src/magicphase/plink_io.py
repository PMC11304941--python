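"""PLINK flat-file input and tabular output.

Reads PED files (pedigree columns + two allele columns per SNP, alleles
coded 0 = missing, 1 = major, 2 = minor) and 4-column MAP files
(chromosome, marker id, genetic distance — ignored — and physical bp).
Also serializes the pipeline's phase, origin and recombination-event
tables as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    ALLELE_MISSING,
    HOMOLOGS,
    ORIGIN_CHARS,
    STATE_TOKENS,
    ST_IMPUTED,
    ST_RESOLVED,
)

log = logging.getLogger(__name__)

VALID_ALLELES = {0, 1, 2}


class PlinkParseError(ValueError):
    """Malformed PED/MAP content."""


class PedigreeStructureError(ValueError):
    """Missing parents, cycles, or other pedigree inconsistencies."""


@dataclass(frozen=True)
class PedigreeRecord:
    iid: str
    father: str | None
    mother: str | None
    family: str = "FAM"
    sex: str = "0"
    phenotype: str = "0"


@dataclass
class Pedigree:
    """Individuals with parent links and derived generation indices.

    Founders (no named parents) are generation 0; every other individual
    sits one generation above its deepest parent. The pedigree must be a
    DAG and every named parent must be present.
    """

    records: list[PedigreeRecord]
    generation: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.generation:
            self.generation = _compute_generations(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.iid for r in self.records]

    def record(self, iid: str) -> PedigreeRecord:
        return self._index()[iid]

    def _index(self) -> dict[str, PedigreeRecord]:
        if not hasattr(self, "_idx"):
            self._idx = {r.iid: r for r in self.records}
        return self._idx

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        r = self.record(iid)
        return r.father, r.mother

    def is_founder(self, iid: str) -> bool:
        return self.generation[iid] == 0

    def founders(self) -> list[str]:
        return [r.iid for r in self.records if self.generation[r.iid] == 0]

    def by_generation(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for r in self.records:
            out.setdefault(self.generation[r.iid], []).append(r.iid)
        return dict(sorted(out.items()))

    @property
    def max_generation(self) -> int:
        return max(self.generation.values())


def _compute_generations(records: list[PedigreeRecord]) -> dict[str, int]:
    index = {r.iid: r for r in records}
    if len(index) != len(records):
        dupes = [r.iid for r in records if sum(s.iid == r.iid for s in records) > 1]
        raise PedigreeStructureError(f"duplicate individual id(s): {sorted(set(dupes))}")
    for r in records:
        for pid in (r.father, r.mother):
            if pid is not None and pid not in index:
                raise PedigreeStructureError(
                    f"individual {r.iid!r} names absent parent {pid!r}"
                )
    gen: dict[str, int] = {}
    ACTIVE = object()
    state: dict[str, object] = {}

    def depth(iid: str) -> int:
        if iid in gen:
            return gen[iid]
        if state.get(iid) is ACTIVE:
            raise PedigreeStructureError(f"pedigree cycle involving {iid!r}")
        state[iid] = ACTIVE
        r = index[iid]
        parents = [p for p in (r.father, r.mother) if p is not None]
        g = 0 if not parents else 1 + max(depth(p) for p in parents)
        gen[iid] = g
        state[iid] = None
        return g

    for r in records:
        depth(r.iid)
    return gen


@dataclass
class GenotypeTable:
    """Unphased diploid genotypes: individuals x loci allele pairs.

    Pairs are stored unordered (sorted ascending); a genotype with one
    missing allele is promoted to fully missing because the Mendelian
    machinery needs both alleles.
    """

    individuals: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n_individuals, n_loci, 2) int8, rows sorted pairs

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("allele array shape does not match ids/loci")
        self._row = {iid: i for i, iid in enumerate(self.individuals)}

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def __contains__(self, iid: str) -> bool:
        return iid in self._row

    def genotype(self, iid: str) -> np.ndarray:
        """Allele pairs (n_loci, 2) for one individual."""
        return self.alleles[self._row[iid]]

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(list(self.individuals), list(self.loci), self.alleles.copy())

    def subset_loci(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        loci = [m for m, k in zip(self.loci, keep) if k]
        return GenotypeTable(list(self.individuals), loci, self.alleles[:, keep, :])


@dataclass
class MarkerMap:
    """Per-locus chromosome, marker id and physical position (bp).

    Loci are grouped by chromosome (order of first appearance) and sorted
    by bp within each chromosome; positions must be unique per chromosome.
    """

    table: pd.DataFrame  # columns: chrom, marker, bp

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["chrom", "marker", "bp"]:
            raise ValueError("MarkerMap table needs columns chrom, marker, bp")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise PlinkParseError(f"duplicate marker id {dup!r}")
        for chrom, grp in t.groupby("chrom", sort=False):
            if grp["bp"].duplicated().any():
                bp = int(grp.loc[grp["bp"].duplicated(), "bp"].iloc[0])
                raise PlinkParseError(f"duplicate bp {bp} on chromosome {chrom}")
        chrom_order = {c: i for i, c in enumerate(t["chrom"].drop_duplicates())}
        order = t.assign(_c=t["chrom"].map(chrom_order)).sort_values(
            ["_c", "bp"], kind="stable"
        )
        if not order.index.equals(t.index):
            log.warning("MAP loci were not sorted by position; reordering")
        self.table = order.drop(columns="_c").reset_index(drop=True)

    @property
    def n_loci(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def positions(self) -> np.ndarray:
        return self.table["bp"].to_numpy(dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def chrom_slices(self) -> list[tuple[str, int, int]]:
        """Contiguous (chrom, start, stop) index ranges, stop exclusive."""
        out = []
        chroms = self.table["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], start, i))
                start = i
        return out

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.loc[np.asarray(keep, bool)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_ped(path, marker_count: int) -> tuple[Pedigree, GenotypeTable]:
    """Parse a PED file into a pedigree and a genotype table.

    Each row must have 6 + 2*marker_count whitespace-separated fields.
    Parent id "0" means founder-parent-absent. Sex and phenotype columns
    are read and ignored. Half-missing genotypes become fully missing.
    """
    records: list[PedigreeRecord] = []
    rows: list[np.ndarray] = []
    expected = 6 + 2 * marker_count
    n_half = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != expected:
                raise PlinkParseError(
                    f"{path}:{lineno}: expected {expected} fields, got {len(fields)}"
                )
            fam, iid, fa, mo, sex, phe = fields[:6]
            try:
                codes = np.array([int(x) for x in fields[6:]], dtype=np.int8)
            except ValueError as e:
                raise PlinkParseError(f"{path}:{lineno}: non-integer allele code ({e})")
            if not np.isin(codes, (0, 1, 2)).all():
                bad = codes[~np.isin(codes, (0, 1, 2))][0]
                raise PlinkParseError(
                    f"{path}:{lineno}: allele code {bad} outside {{0,1,2}}"
                )
            pair = codes.reshape(marker_count, 2)
            half = (pair == ALLELE_MISSING).any(axis=1) & (
                pair != ALLELE_MISSING
            ).any(axis=1)
            if half.any():
                n_half += int(half.sum())
                pair = pair.copy()
                pair[half] = ALLELE_MISSING
            pair = np.sort(pair, axis=1)
            records.append(
                PedigreeRecord(
                    iid=iid,
                    father=None if fa == "0" else fa,
                    mother=None if mo == "0" else mo,
                    family=fam,
                    sex=sex,
                    phenotype=phe,
                )
            )
            rows.append(pair)
    if n_half:
        log.warning("%d half-missing genotypes promoted to fully missing", n_half)
    pedigree = Pedigree(records)
    loci = [f"snp{i + 1}" for i in range(marker_count)]
    alleles = (
        np.stack(rows) if rows else np.empty((0, marker_count, 2), dtype=np.int8)
    )
    genotypes = GenotypeTable([r.iid for r in records], loci, alleles)
    return pedigree, genotypes


def read_map(path) -> MarkerMap:
    """Parse a 4-column PLINK MAP file; the genetic-distance column is ignored."""
    chroms, markers, bps = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PlinkParseError(
                    f"{path}:{lineno}: expected 4 MAP columns, got {len(fields)}"
                )
            chrom, marker, _gendist, bp = fields
            try:
                bp_val = int(bp)
            except ValueError:
                raise PlinkParseError(f"{path}:{lineno}: non-numeric bp {bp!r}")
            if bp_val <= 0:
                raise PlinkParseError(f"{path}:{lineno}: non-positive bp {bp_val}")
            chroms.append(chrom)
            markers.append(marker)
            bps.append(bp_val)
    table = pd.DataFrame({"chrom": chroms, "marker": markers, "bp": bps})
    return MarkerMap(table)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_ped(pedigree: Pedigree, genotypes: GenotypeTable, path) -> None:
    with open(path, "w") as fh:
        for r in pedigree.records:
            pair = genotypes.genotype(r.iid).reshape(-1)
            fields = [
                r.family,
                r.iid,
                r.father or "0",
                r.mother or "0",
                r.sex,
                r.phenotype,
            ] + [str(int(a)) for a in pair]
            fh.write(" ".join(fields) + "\n")


def write_map(marker_map: MarkerMap, path) -> None:
    with open(path, "w") as fh:
        for row in marker_map.table.itertuples(index=False):
            fh.write(f"{row.chrom} {row.marker} 0 {row.bp}\n")


def _phase_tokens(allele: np.ndarray, state: np.ndarray) -> list[str]:
    out = []
    for a, s in zip(allele, state):
        if s in (ST_RESOLVED, ST_IMPUTED):
            out.append(str(int(a)))
        else:
            out.append(STATE_TOKENS[int(s)])
    return out


def write_tables(phases, origins, events, out_prefix, marker_map=None, founders=None):
    """Serialize phase, origin and event tables as TSV.

    Produces ``<prefix>.phases.tsv`` (per-homolog allele/tag token strings),
    ``<prefix>.origins.tsv`` (per-homolog origin character strings) and
    ``<prefix>.events.tsv``. All structures must share locus ordering.
    Returns the list of paths written.
    """
    n_loci = None
    for ph in phases.values():
        n_loci = ph.n_loci
        break
    for mo in origins.values():
        if n_loci is not None and mo.n_loci != n_loci:
            raise ValueError("phase/origin tables disagree on locus count")
    if marker_map is not None and n_loci is not None and marker_map.n_loci != n_loci:
        raise ValueError("marker map length does not match phased tables")

    paths = []
    p_phases = f"{out_prefix}.phases.tsv"
    with open(p_phases, "w") as fh:
        fh.write("individual\thomolog\tphase\n")
        for iid, ph in phases.items():
            for hom in HOMOLOGS:
                tokens = _phase_tokens(ph.allele(hom), ph.state(hom))
                fh.write(f"{iid}\t{hom}\t{' '.join(tokens)}\n")
    paths.append(p_phases)

    p_origins = f"{out_prefix}.origins.tsv"
    with open(p_origins, "w") as fh:
        fh.write("individual\thomolog\torigins\n")
        for iid, mo in origins.items():
            for hom in HOMOLOGS:
                chars = "".join(ORIGIN_CHARS[int(o)] for o in mo.origin(hom))
                fh.write(f"{iid}\t{hom}\t{chars}\n")
    paths.append(p_origins)

    p_events = f"{out_prefix}.events.tsv"
    with open(p_events, "w") as fh:
        cols = [
            "individual",
            "meiosis",
            "chrom",
            "start_marker",
            "end_marker",
            "start_bp",
            "end_bp",
            "n_intervals",
            "left_origin",
            "right_origin",
            "class",
            "founder_left",
            "founder_right",
        ]
        fh.write("\t".join(cols) + "\n")
        for ev in events:
            f_left = f_right = "NA"
            if founders is not None and ev.individual in founders:
                fa = founders[ev.individual]
                f_left = fa.founder(ev.homolog, ev.start_idx) or "NA"
                f_right = fa.founder(ev.homolog, ev.end_idx) or "NA"
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        ev.individual,
                        ev.homolog,
                        ev.chrom,
                        ev.start_marker,
                        ev.end_marker,
                        ev.start_bp,
                        ev.end_bp,
                        ev.n_intervals,
                        ORIGIN_CHARS[ev.left_origin],
                        ORIGIN_CHARS[ev.right_origin],
                        ev.klass,
                        f_left,
                        f_right,
                    ]
                )
                + "\n"
            )
    paths.append(p_events)
    return paths
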