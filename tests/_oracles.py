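"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: windows are enumerated
explicitly, patterns are counted in dictionaries, and indices come from an
explicit list of permutations.
"""

import itertools
import math

import numpy as np


def _pattern_of(window):
    """Rank vector: highest amplitude -> rank 1; ties -> earlier sample wins."""
    n = len(window)
    order = sorted(range(n), key=lambda i: (-window[i], i))
    ranks = [0] * n
    for r, i in enumerate(order):
        ranks[i] = r + 1
    return tuple(ranks)


def _perm_index(pattern):
    n = len(pattern)
    perms = list(itertools.permutations(range(1, n + 1)))
    return perms.index(tuple(pattern))


def brute_symbols(x, n, tau):
    return [
        _perm_index(_pattern_of([x[t + k * tau] for k in range(n)]))
        for t in range(len(x) - (n - 1) * tau)
    ]


def brute_pe(x, n, tau):
    symbols = brute_symbols(x, n, tau)
    counts = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    total = len(symbols)
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(n))


def brute_mirror(symbol, n):
    perms = list(itertools.permutations(range(1, n + 1)))
    pattern = perms[symbol]
    return perms.index(tuple(n + 1 - r for r in pattern))


def brute_jpe_inv(x, y, n, tau):
    sx = brute_symbols(x, n, tau)
    sy = brute_symbols(y, n, tau)
    counts = {}
    for a, b in zip(sx, sy):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    total = sum(counts.values())
    nf = math.factorial(n)
    excluded = {(a, a) for a in range(nf)} | {(a, brute_mirror(a, n)) for a in range(nf)}
    retained = {k: v for k, v in counts.items() if k not in excluded}
    mass = sum(retained.values()) / total
    if mass < 1e-9:
        return 0.0
    h = 0.0
    for v in retained.values():
        p = v / total / mass
        h -= p * math.log(p)
    jpe = h / math.log(nf * nf - len(excluded))
    return min(1.0, max(0.0, 1.0 - jpe))


def step_up_bh(p):
    """Benjamini-Hochberg step-up, written from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def exhaustive_permutation_p(a, b):
    """Exact two-sided permutation p-value (|mean diff|) over all partitions
    of the pooled subjects into groups of the original sizes, per column."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    pooled = np.vstack([a, b])
    n_a = a.shape[0]
    idx = range(pooled.shape[0])
    t_obs = np.abs(a.mean(axis=0) - b.mean(axis=0))
    count = np.zeros(pooled.shape[1])
    n_part = 0
    for comb in itertools.combinations(idx, n_a):
        sel = np.zeros(pooled.shape[0], dtype=bool)
        sel[list(comb)] = True
        t = np.abs(pooled[sel].mean(axis=0) - pooled[~sel].mean(axis=0))
        count += t >= t_obs - 1e-12
        n_part += 1
    return count / n_part
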