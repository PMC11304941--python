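"""Independent brute-force oracles for origin inference and haploblock filtering.

Pure-Python, list-based re-derivations of the origin rules, kept free of
the package's vectorized code paths so they can serve as a second,
independent route in equivalence tests.
"""

from __future__ import annotations


def oracle_complete(chars: list[str]) -> list[str]:
    """Fill noninformative runs between same-origin flanks or at borders."""
    out = list(chars)
    idx = [i for i, c in enumerate(out) if c in "PM"]
    if not idx:
        return out
    for i in range(idx[0]):
        out[i] = out[idx[0]]
    for i in range(idx[-1] + 1, len(out)):
        out[i] = out[idx[-1]]
    for a, b in zip(idx, idx[1:]):
        if out[a] == out[b]:
            for i in range(a + 1, b):
                out[i] = out[a]
    return out


def oracle_blocks(chars: list[str]) -> list[tuple[str, int, int]]:
    """Maximal runs of assigned origin as (origin, start, end) inclusive."""
    blocks = []
    i = 0
    n = len(chars)
    while i < n:
        if chars[i] in "PM":
            j = i
            while j + 1 < n and chars[j + 1] == chars[i]:
                j += 1
            blocks.append((chars[i], i, j))
            i = j + 1
        else:
            i += 1
    return blocks


def oracle_filter(
    chars: list[str], informative: list[bool], min_count: int
) -> tuple[list[str], list[bool]]:
    """Complete, then sweep-remove below-min blocks to a fixpoint."""
    chars = oracle_complete(chars)
    informative = list(informative)
    while True:
        removed = False
        for origin, s, e in oracle_blocks(chars):
            if sum(informative[s:e + 1]) < min_count:
                for i in range(s, e + 1):
                    chars[i] = "*"
                    informative[i] = False
                removed = True
        if not removed:
            return chars, informative
        chars = oracle_complete(chars)


def oracle_trio_locus(fa_alleles, fb_alleles, fc_alleles, fd_alleles, child_gt):
    """Origin characters and informativeness of one trio-chain locus.

    Founders A, B (parents of E) and C, D (parents of F) each contribute a
    single homozygous allele (0 = ungenotyped); the G2 child of E x F has
    genotype ``child_gt``. Returns ((pat_char, pat_inf), (mat_char, mat_inf))
    for the child's pre-completion origin assignment.
    """
    fA, fB, fC, fD = fa_alleles, fb_alleles, fc_alleles, fd_alleles
    e_gt = tuple(sorted((fA, fB))) if 0 not in (fA, fB) else (0, 0)
    f_gt = tuple(sorted((fC, fD))) if 0 not in (fC, fD) else (0, 0)
    o1, o2 = child_gt

    def carries(gt, a):
        return a in gt

    if 0 in e_gt or 0 in f_gt or 0 in child_gt:
        return (("?", False), ("?", False))
    if o1 == o2:
        if carries(e_gt, o1) and carries(f_gt, o1):
            pat_allele = mat_allele = o1
        else:
            return (("!", False), ("!", False))
    else:
        a1 = carries(e_gt, o1) and carries(f_gt, o2)
        a2 = carries(e_gt, o2) and carries(f_gt, o1)
        if a1 and a2:
            return (("?", False), ("?", False))
        if not a1 and not a2:
            return (("!", False), ("!", False))
        pat_allele, mat_allele = (o1, o2) if a1 else (o2, o1)

    def origin_vs_parent(allele, p_allele, m_allele):
        if p_allele == m_allele:
            return ("*", False)
        if allele == p_allele:
            return ("P", True)
        if allele == m_allele:
            return ("M", True)
        return ("!", False)

    return (
        origin_vs_parent(pat_allele, fA, fB),
        origin_vs_parent(mat_allele, fC, fD),
    )
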