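"""Shared fixtures: a hand-built 3-generation family and mosaic helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from magicphase.constants import CHAR_ORIGINS
from magicphase.origins import OriginMosaic
from magicphase.plink_io import MarkerMap

# ---------------------------------------------------------------------------
# An 8-member, 10-SNP, 3-generation family (G0 founders A-D, G1 E/F, G2 X/Y).
#
# Founder haplotypes (homozygous):
#   A: 1 1 1 1 1 1 1 1 1 1
#   B: 2 2 2 2 2 1 2 2 2 2
#   C: 1 2 1 2 1 2 1 2 1 2
#   D: 2 1 2 1 2 1 2 1 2 2
# X inherits A-haplotype loci 0-4 then B-haplotype loci 5-9 from E
# (one paternal crossover between bp 500 and 600) and the C-haplotype
# from F throughout. Hand edits: locus 5 of X is a Mendelian error
# (2/2 where E carries only 1s), locus 7 is missing.
# ---------------------------------------------------------------------------

FOUNDER_HAPS = {
    "A": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "B": [2, 2, 2, 2, 2, 1, 2, 2, 2, 2],
    "C": [1, 2, 1, 2, 1, 2, 1, 2, 1, 2],
    "D": [2, 1, 2, 1, 2, 1, 2, 1, 2, 2],
}


def _pair(a, b):
    return [tuple(sorted(p)) for p in zip(a, b)]


def family_genotypes() -> dict[str, list[tuple[int, int]]]:
    h = FOUNDER_HAPS
    gt = {k: _pair(v, v) for k, v in h.items()}
    gt["E"] = _pair(h["A"], h["B"])
    gt["F"] = _pair(h["C"], h["D"])
    x_pat = h["A"][:5] + h["B"][5:]
    x_mat = h["C"]
    gt["X"] = _pair(x_pat, x_mat)
    gt["X"][5] = (2, 2)  # Mendelian error: E is 1/1 at locus 5
    gt["X"][7] = (0, 0)  # missing data
    y_pat = h["B"]
    y_mat = h["C"][:8] + h["D"][8:]
    gt["Y"] = _pair(y_pat, y_mat)
    return gt


FAMILY_PARENTS = {
    "A": ("0", "0"),
    "B": ("0", "0"),
    "C": ("0", "0"),
    "D": ("0", "0"),
    "E": ("A", "B"),
    "F": ("C", "D"),
    "X": ("E", "F"),
    "Y": ("E", "F"),
}


def family_ped_text() -> str:
    gt = family_genotypes()
    lines = []
    for iid, (fa, mo) in FAMILY_PARENTS.items():
        alleles = " ".join(f"{a} {b}" for a, b in gt[iid])
        lines.append(f"FAM {iid} {fa} {mo} 0 0 {alleles}")
    return "\n".join(lines) + "\n"


def family_map_text() -> str:
    return "".join(f"A01 m{i + 1} 0 {100 * (i + 1)}\n" for i in range(10))


@pytest.fixture
def family_files(tmp_path):
    ped = tmp_path / "family.ped"
    mp = tmp_path / "family.map"
    ped.write_text(family_ped_text())
    mp.write_text(family_map_text())
    return ped, mp


@pytest.fixture
def family_map() -> MarkerMap:
    return MarkerMap(
        pd.DataFrame(
            {
                "chrom": ["A01"] * 10,
                "marker": [f"m{i + 1}" for i in range(10)],
                "bp": [100 * (i + 1) for i in range(10)],
            }
        )
    )


# ---------------------------------------------------------------------------
# Mosaic helpers
# ---------------------------------------------------------------------------

def mosaic_from_strings(
    pat: str, mat: str | None = None, pat_inf=None, mat_inf=None
) -> OriginMosaic:
    """Build a mosaic from origin character strings like "PP*?M".

    By default every P/M locus is informative.
    """
    if mat is None:
        mat = "*" * len(pat)

    def conv(s, inf):
        origin = np.array([CHAR_ORIGINS[c] for c in s], np.int8)
        if inf is None:
            informative = np.array([c in "PM" for c in s])
        else:
            informative = np.asarray(inf, bool)
        return origin, informative

    po, pi = conv(pat, pat_inf)
    mo, mi = conv(mat, mat_inf)
    return OriginMosaic(po, mo, pi, mi)


def origin_string(mosaic: OriginMosaic, homolog: str = "paternal") -> str:
    from magicphase.constants import ORIGIN_CHARS

    return "".join(ORIGIN_CHARS[int(o)] for o in mosaic.origin(homolog))
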