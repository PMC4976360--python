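"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exact rational arithmetic, direct
enumeration and spreadsheet-style formula evaluation, sharing no code with
the implementation under test.
"""

from fractions import Fraction
from math import comb

TIE_TOL = Fraction(1, 10**7)


def fisher_2x3_tables(c0: int, c1: int, c2: int, nf: int):
    """All (female_row, male_row) pairs with the given margins."""
    n = c0 + c1 + c2
    nm = n - nf
    for f0 in range(max(0, c0 - nm), min(c0, nf) + 1):
        for f1 in range(0, min(c1, nf - f0) + 1):
            f2 = nf - f0 - f1
            if 0 <= f2 <= c2 and (c1 - f1) <= nm and (c2 - f2) <= nm:
                if (c0 - f0) + (c1 - f1) + (c2 - f2) == nm:
                    yield (f0, f1, f2), (c0 - f0, c1 - f1, c2 - f2)


def fisher_2x3_exact(female, male) -> Fraction:
    """Exact rational two-sided p of the 2×3 genotype-by-sex Fisher test.

    Sums the point probabilities of every same-margin table whose point
    probability is at most (1 + 1e-7) times the observed one, all in
    integer/rational arithmetic.
    """
    f0, f1, f2 = female
    m0, m1, m2 = male
    nf, nm = f0 + f1 + f2, m0 + m1 + m2
    n = nf + nm
    c0, c1, c2 = f0 + m0, f1 + m1, f2 + m2
    w_obs = comb(c0, f0) * comb(c1, f1) * comb(c2, f2)
    cutoff = (1 + TIE_TOL) * w_obs
    total = 0
    for (a0, a1, a2), _ in fisher_2x3_tables(c0, c1, c2, nf):
        w = comb(c0, a0) * comb(c1, a1) * comb(c2, a2)
        if w <= cutoff:
            total += w
    return Fraction(total, comb(n, nf))


def inbreeding_f_exact(panel_codes, sample_col, correction=True):
    """Spreadsheet-style rational evaluation of the inbreeding coefficient.

    ``panel_codes``: list of per-locus genotype code lists (0 hom-ref, 1 het,
    2 hom-alt, 3 missing) over the whole cohort; ``sample_col``: column of
    the focal individual.  Returns (O_hom, E_hom, L, F) as exact rationals,
    or None for F when undefined.
    """
    o_hom = 0
    e_hom = Fraction(0)
    l_sites = 0
    for row in panel_codes:
        called = [g for g in row if g != 3]
        n = len(called)
        if n < 2:
            continue
        alt = sum(1 for g in called if g == 1) + 2 * sum(1 for g in called if g == 2)
        p = Fraction(alt, 2 * n)
        if p == 0 or p == 1:
            continue
        g_self = row[sample_col]
        if g_self == 3:
            continue
        corr = Fraction(2 * n, 2 * n - 1) if correction else Fraction(1)
        e_hom += 1 - 2 * p * (1 - p) * corr
        l_sites += 1
        if g_self in (0, 2):
            o_hom += 1
    if l_sites == 0 or l_sites == e_hom:
        return o_hom, e_hom, l_sites, None
    return o_hom, e_hom, l_sites, Fraction(o_hom - e_hom, 1) / (l_sites - e_hom)


def snp_indel_distance(snp_pos: int, indel_pos: int, indel_ref_len: int) -> int:
    """Minimum |snp_pos - q| over every base q of the indel's REF footprint."""
    return min(abs(snp_pos - q) for q in range(indel_pos, indel_pos + indel_ref_len))
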