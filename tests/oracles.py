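"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: exact-test
p-values by exhaustive hypergeometric enumeration with rational
arithmetic, step-up FDR by direct computation, and the running-sum
enrichment score by a plain walk down the list.
"""

from fractions import Fraction
from math import comb


def hypergeom_pmf_exact(a: int, row1: int, col1: int, n: int) -> Fraction:
    """P(cell_11 = a) for a 2x2 table with margins row1, col1, total n."""
    if a < max(0, row1 + col1 - n) or a > min(row1, col1):
        return Fraction(0)
    return Fraction(comb(col1, a) * comb(n - col1, row1 - a), comb(n, row1))


def one_sided_p_enumeration(ip: int, inp: int, total_ip: int, total_input: int) -> float:
    """Upper-tail p of the window enrichment table by exhaustive enumeration."""
    n = total_ip + total_input
    col1 = ip + inp          # reads in this window
    row1 = total_ip          # IP pool
    p = Fraction(0)
    for a in range(ip, min(row1, col1) + 1):
        p += hypergeom_pmf_exact(a, row1, col1, n)
    return float(min(p, Fraction(1)))


def two_sided_p_enumeration(ip_b: int, input_b: int, ip_a: int, input_a: int) -> float:
    """Two-sided exact p: sum of table probabilities <= the observed one."""
    n = ip_b + input_b + ip_a + input_a
    if n == 0:
        return 1.0
    row1 = ip_b + input_b
    col1 = ip_b + ip_a
    p_obs = hypergeom_pmf_exact(ip_b, row1, col1, n)
    p = Fraction(0)
    for a in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pa = hypergeom_pmf_exact(a, row1, col1, n)
        if pa <= p_obs:
            p += pa
    return float(min(p, Fraction(1)))


def bh_stepup_direct(pvals):
    """Benjamini-Hochberg step-up computed from its definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running_min = min(running_min, pvals[i] * m / rank)
        q[i] = running_min
    return q


def enrichment_score_walk(genes, scores, members, weight_p=1.0):
    """Direct running-sum walk: the ES is the extreme running value."""
    hits = [abs(s) ** weight_p if g in members else 0.0 for g, s in zip(genes, scores)]
    n_hits = sum(1 for g in genes if g in members)
    n_miss = len(genes) - n_hits
    denom = sum(hits)
    running, best = 0.0, 0.0
    for g, h in zip(genes, hits):
        if g in members:
            running += h / denom
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best
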