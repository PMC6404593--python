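"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a statistic by direct enumeration or the raw
textbook formula, deliberately sharing no code with the implementation it
checks.
"""

import math

import numpy as np


def pairwise_diff_pi_sum(dosages: np.ndarray) -> float:
    """Sum over sites of average pairwise differences, by explicit
    chromosome-pair enumeration from dosage rows (missing = -1 excluded)."""
    total = 0.0
    for row in dosages:
        called = row[row >= 0]
        if called.size < 1:
            continue
        # expand each diploid genotype into two alleles
        alleles = []
        for d in called:
            if d == 0:
                alleles += [0, 0]
            elif d == 1:
                alleles += [0, 1]
            else:
                alleles += [1, 1]
        n = len(alleles)
        if n < 2:
            continue
        diff = 0
        for a in range(n):
            for b in range(a + 1, n):
                diff += alleles[a] != alleles[b]
        total += diff / (n * (n - 1) / 2)
    return total


def tajimas_d_direct(dosages: np.ndarray) -> float:
    """Tajima's D by the raw formula, assuming no missing genotypes."""
    assert (dosages >= 0).all()
    n = 2 * dosages.shape[1]
    alt = dosages.sum(axis=1)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    k_hat = pairwise_diff_pi_sum(dosages[seg])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration over heterozygote counts using
    integer combinatorics (conditional on allele counts)."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    def weight(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        return (
            math.factorial(n)
            // (math.factorial(hr) * math.factorial(h) * math.factorial(hc))
            * 2**h
        )

    hets = list(range(rare % 2, rare + 1, 2))
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= w_obs) / total


def hypergeom_upper_tail(k: int, q: int, t: int, U: int) -> float:
    """P(X >= k) for overlap of a size-q and size-t subset of U, by direct
    integer summation."""
    denom = math.comb(U, q)
    num = sum(
        math.comb(t, x) * math.comb(U - t, q - x)
        for x in range(k, min(q, t) + 1)
    )
    return num / denom


def stubb_enumeration(seq, matrix, bg, t):
    """Partition-function window score by recursive enumeration of all
    non-overlapping motif placements (both strands)."""
    seq = np.asarray(seq)
    w = matrix.shape[0]
    rc = matrix[::-1, ::-1]
    L = len(seq)

    def pw(mat, sub):
        p = 1.0
        for i, b in enumerate(sub):
            p *= mat[i, b]
        return p

    def rec(i):
        if i == L:
            return 1.0
        total = (1 - t) * bg[seq[i]] * rec(i + 1)
        if i + w <= L:
            sub = seq[i : i + w]
            total += (t / 2.0) * (pw(matrix, sub) + pw(rc, sub)) * rec(i + w)
        return total

    log_bg = sum(math.log(bg[b]) for b in seq)
    return math.log(rec(0)) - log_bg
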