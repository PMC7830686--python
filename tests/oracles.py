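"""Independent brute-force reference implementations of the nonlinear
measures, written directly from their definitions: explicit per-template
loops with direct Chebyshev-distance evaluation and pair counting.  They
share no code with the optimized kernels (which compute template matches
from shifted diagonals of a scalar match matrix)."""

import math

import numpy as np


def _windows(u, m, delay=1):
    n = len(u) - (m - 1) * delay
    return np.array(
        [u[i : i + (m - 1) * delay + 1 : delay] for i in range(n)], dtype=float
    )


def oracle_apen(u, m, r):
    def phi(mm):
        X = _windows(u, mm)
        n = len(X)
        acc = 0.0
        for i in range(n):  # self-match included
            d = np.max(np.abs(X - X[i]), axis=1)
            acc += math.log(int((d <= r).sum()) / n)
        return acc / n

    return phi(m) - phi(m + 1)


def oracle_sampen(u, m, r):
    def mean_match_fraction(X):
        n = len(X)
        total = 0.0
        for i in range(n):
            d = np.max(np.abs(X - X[i]), axis=1)
            total += (int((d <= r).sum()) - 1) / (n - 1)  # exclude the self-match
        return total / n

    B = mean_match_fraction(_windows(u, m))
    A = mean_match_fraction(_windows(u, m + 1))
    if A == 0 or B == 0:
        return math.inf
    return -math.log(A / B)


def oracle_fuzzyen(u, m, r):
    def phi(mm):
        X = _windows(u, mm)
        X = X - X.mean(axis=1, keepdims=True)
        n = len(X)
        acc = 0.0
        for i in range(n):
            d = np.max(np.abs(X - X[i]), axis=1)
            sim = np.exp(-math.log(2.0) * (d / r) ** 2)
            acc += (float(sim.sum()) - 1.0) / (n - 1)  # exclude self-similarity
        return acc / n

    return math.log(phi(m)) - math.log(phi(m + 1))


def oracle_permen(u, order, delay=1):
    patterns = {}
    for w in _windows(u, order, delay):
        # ascending rank order, ties broken by subscript
        pat = tuple(sorted(range(order), key=lambda k: (w[k], k)))
        patterns[pat] = patterns.get(pat, 0) + 1
    total = sum(patterns.values())
    return -sum((c / total) * math.log(c / total) for c in patterns.values())


def oracle_recurrence(u, m, delay, eps, lmin):
    X = _windows(u, m, delay)
    n = len(X)
    R = np.zeros((n, n), dtype=bool)
    for i in range(n):
        R[i] = np.max(np.abs(X - X[i]), axis=1) <= eps
        R[i, i] = False
    total = int(R.sum())
    if total == 0:
        return 0.0, 0.0
    rr = total / (n * (n - 1))
    on_lines = 0
    for k in range(-(n - 1), n):  # scan every off-main diagonal for runs
        if k == 0:
            continue
        cells = [R[i, i + k] for i in range(n) if 0 <= i + k < n]
        run = 0
        for cell in cells + [False]:
            if cell:
                run += 1
            else:
                if run >= lmin:
                    on_lines += run
                run = 0
    return rr, on_lines / total
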