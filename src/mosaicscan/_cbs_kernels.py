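"""Numerical kernels for circular binary segmentation.

The maximal arc statistic scans every arc of the circularly extended
segment and compares the arc mean with the complement mean; because the
statistic is symmetric in arc/complement, only non-wrapping arcs need to be
enumerated. The permutation kernel reshuffles the values in place
(Fisher-Yates on numba's own seeded RNG) and counts permuted maxima that
reach the observed one, stopping early once the exceedance count already
guarantees p >= alpha.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def max_arc_stat(x, min_width):
    """Return (raw_stat, i, j) maximizing |S_arc - k*mean| / sqrt(k(n-k)/n).

    The arc is x[i:j] (half-open); both arc and complement have at least
    ``min_width`` points. The raw statistic equals the standardized
    two-sample mean difference times the sample SD (which is permutation
    invariant and divided out by the caller when needed).
    """
    n = x.shape[0]
    S = np.empty(n + 1)
    S[0] = 0.0
    for t in range(n):
        S[t + 1] = S[t] + x[t]
    tot = S[n]
    best = -1.0
    bi = 0
    bj = n
    for k in range(min_width, n - min_width + 1):
        denom = np.sqrt(k * (n - k) / n)
        mu_k = k * tot / n
        for i in range(0, n - k + 1):
            v = abs(S[i + k] - S[i] - mu_k) / denom
            if v > best:
                best = v
                bi = i
                bj = i + k
    return best, bi, bj


@njit(cache=False)
def _max_stat_only(x, min_width):
    n = x.shape[0]
    S = np.empty(n + 1)
    S[0] = 0.0
    for t in range(n):
        S[t + 1] = S[t] + x[t]
    tot = S[n]
    best = -1.0
    for k in range(min_width, n - min_width + 1):
        denom = np.sqrt(k * (n - k) / n)
        mu_k = k * tot / n
        for i in range(0, n - k + 1):
            v = abs(S[i + k] - S[i] - mu_k) / denom
            if v > best:
                best = v
    return best


@njit(cache=False)
def perm_exceedances(x, observed, min_width, n_perm, max_exceed, seed):
    """Count permuted max statistics >= observed.

    Returns (n_done, n_exceed); stops as soon as n_exceed > max_exceed,
    at which point the split is already non-significant at the chosen
    alpha. Deterministic for a fixed seed.
    """
    np.random.seed(seed)
    y = x.copy()
    n = y.shape[0]
    exceed = 0
    for p in range(n_perm):
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = y[i]
            y[i] = y[j]
            y[j] = tmp
        if _max_stat_only(y, min_width) >= observed:
            exceed += 1
            if exceed > max_exceed:
                return p + 1, exceed
    return n_perm, exceed
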