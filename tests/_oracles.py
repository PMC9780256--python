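"""Independent oracles shared by unit and acceptance tests.

These deliberately re-derive quantities along a different code path than
the implementation: the partition optimum by memoization-free recursion,
the Poisson-binomial distribution by exact convolution, and binomial
log-likelihoods written out directly.
"""

import math

import numpy as np

from patmut.iupac import IUPAC_SETS, TWO_PARTITIONS, expand


def table_counts(table):
    """kmer -> (m, u) dict for a count table."""
    return {kmer: (m, u) for kmer, m, u in table.items(nonzero_only=False)}


def pattern_counts(pattern, counts):
    M = U = 0
    for kmer in expand(pattern):
        m, u = counts.get(kmer, (0, 0))
        M += m
        U += u
    return M, U


def single_pattern_loss(pattern, counts, alpha, c, mu):
    M, U = pattern_counts(pattern, counts)
    denom = M + U + (alpha / mu if alpha > 0 else 0.0)
    r = mu if denom == 0 else (M + alpha) / denom
    ll = 0.0
    if M > 0:
        ll += M * math.log(r)
    if U > 0:
        ll += U * math.log1p(-r)
    return -2.0 * ll + c


def brute_force_min_loss(root, counts, alpha, c, mu):
    """Minimal partition loss by exhaustive recursion (no memoization)."""

    def f(p):
        best = single_pattern_loss(p, counts, alpha, c, mu)
        for i, code in enumerate(p):
            for x, y in TWO_PARTITIONS.get(code, ()):
                cand = f(p[:i] + x + p[i + 1:]) + f(p[:i] + y + p[i + 1:])
                if cand < best:
                    best = cand
        return best

    return f(root)


def exact_poisson_binomial_pmf(probs):
    """PMF of a sum of independent Bernoulli trials by convolution."""
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.zeros(len(pmf) + 1)
        nxt[:-1] += pmf * (1 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def binomial_loglik(M, U, r):
    ll = 0.0
    if M > 0:
        ll += M * math.log(r)
    if U > 0:
        ll += U * math.log1p(-r)
    return ll
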