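"""Independent reference implementations used as test oracles.

These are deliberately naive (quadratic loops, textbook formulas,
exhaustive enumeration) and share no code with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


# -- D'Agostino-Pearson omnibus statistic, from the published formulas ---------

def k2_reference(values) -> float:
    """K² = Z1(skewness)² + Z2(kurtosis)² from the original
    standardizations (D'Agostino 1970; Anscombe & Glynn 1983)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    m4 = ((x - m) ** 4).mean()

    # skewness transform
    b1 = m3 / m2**1.5
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    z1 = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis transform
    b2 = m4 / m2**2
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xstat = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + math.sqrt(1.0 + 4.0 / sqrt_beta1**2))
    term = (1.0 - 2.0 / a) / (1.0 + xstat * math.sqrt(2.0 / (a - 4.0)))
    z2 = ((1.0 - 2.0 / (9.0 * a)) - math.copysign(abs(term) ** (1.0 / 3.0), term)) / math.sqrt(
        2.0 / (9.0 * a)
    )
    return z1**2 + z2**2


def threshold_reference(weights, cutoff: float, min_length: int = 9) -> set:
    """Naive quadratic-time K² stripping: recompute the statistic on the
    survivors each round, removing the largest-|weight| gene (earliest
    index on ties) while the statistic exceeds the cutoff and more than
    ``min_length`` genes survive. Returns the removed (member) gene set."""
    genes = list(weights.index)
    vals = {g: float(weights[g]) for g in genes}
    alive = list(genes)
    removed = []
    while len(alive) > min_length:
        cur = np.array([vals[g] for g in alive])
        if np.ptp(cur) == 0:
            break
        if k2_reference(cur) <= cutoff:
            break
        best = max(alive, key=lambda g: (abs(vals[g]), -genes.index(g)))
        alive.remove(best)
        removed.append(best)
    return set(removed)


# -- two-sided Fisher p by exhaustive hypergeometric enumeration ---------------

def fisher_two_sided_reference(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def log_choose(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    def prob(x):
        return math.exp(
            log_choose(col1, x) + log_choose(n - col1, row1 - x) - log_choose(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1.0 + 1e-9):
            total += px
    return min(total, 1.0)


# -- strand-aware upstream windows, naive re-implementation --------------------

def upstream_regions_reference(genes, contig_lengths, length=200):
    """``genes``: list of (gene_id, contig, start0, end0, strand) with
    0-based half-open coordinates. Returns {gene_id: (lo, hi)} for genes
    whose upstream window fits the contig and overlaps no gene."""
    out = {}
    for gid, contig, start0, end0, strand in genes:
        if strand == "+":
            lo, hi = start0 - length, start0
        else:
            lo, hi = end0, end0 + length
        if lo < 0 or hi > contig_lengths[contig]:
            continue
        clash = False
        for g2, c2, s2, e2, _ in genes:
            if g2 == gid or c2 != contig:
                continue
            if lo < e2 and s2 < hi:
                clash = True
                break
        if not clash:
            out[gid] = (lo, hi)
    return out
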