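"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive — explicit loops, exact rational
arithmetic — and shares no code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hp_brute_force(maj_reads, min_reads) -> float:
    """Pooled heterozygosity by an explicit loop over window SNPs."""
    s_maj = 0
    s_min = 0
    for a, b in zip(maj_reads, min_reads):
        if a + b > 0:
            s_maj += a
            s_min += b
    total = s_maj + s_min
    if total == 0:
        return 0.0
    return 2 * s_maj * s_min / (total * total)


def wc_theta_two_pop(p_list, n_list) -> float:
    """Weir & Cockerham (1984) theta-hat for r allele-frequency samples.

    Literal transcription of the mean-square formulation: MSP (between
    populations), MSG (within), effective sample size n_c.
    """
    r = len(p_list)
    n_tot = sum(n_list)
    p_bar = sum(n * p for n, p in zip(n_list, p_list)) / n_tot
    msp = sum(n * (p - p_bar) ** 2 for n, p in zip(n_list, p_list)) / (r - 1)
    msg = sum(n * p * (1 - p) for n, p in zip(n_list, p_list)) / sum(
        n - 1 for n in n_list
    )
    n_c = (n_tot - sum(n * n for n in n_list) / n_tot) / (r - 1)
    denom = msp + (n_c - 1) * msg
    if denom <= 0:
        return float("nan")
    return (msp - msg) / denom


def hypergeom_upper_tail(overlap, universe, term_size, query_size) -> Fraction:
    """P(X >= overlap) by exhaustive summation of hypergeometric terms."""
    total = comb(universe, query_size)
    num = 0
    for k in range(overlap, min(term_size, query_size) + 1):
        if universe - term_size < query_size - k:
            continue
        num += comb(term_size, k) * comb(universe - term_size, query_size - k)
    return Fraction(num, total)


def fisher_two_sided(a, b, c, d) -> Fraction:
    """Two-sided Fisher exact p for [[a, b], [c, d]].

    Enumerates every table with the same margins and sums the probabilities
    of all tables no more likely than the observed one (the probability-mass
    definition scipy also uses), in exact rational arithmetic.
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    total = comb(n, row1)

    def table_prob(x: int) -> Fraction:
        # x = top-left cell; margins fix the rest
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return Fraction(0)
        return Fraction(comb(col1, x) * comb(n - col1, row1 - x), total)

    p_obs = table_prob(a)
    acc = Fraction(0)
    for x in range(0, min(row1, col1) + 1):
        p = table_prob(x)
        if p <= p_obs:
            acc += p
    return acc


def fisher_margin_pvalues(row1: int, row2: int, col1: int) -> dict[int, Fraction]:
    """Two-sided Fisher p for every table with the given margins, keyed by the
    top-left cell.  Integer weights over the common denominator C(n, row1)."""
    n = row1 + row2
    total = comb(n, row1)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    weights = {x: comb(col1, x) * comb(n - col1, row1 - x) for x in range(lo, hi + 1)}
    out = {}
    for a, wa in weights.items():
        num = sum(w for w in weights.values() if w <= wa)
        out[a] = Fraction(num, total)
    return out
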