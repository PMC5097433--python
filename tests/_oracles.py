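"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written as naive enumeration / direct
arithmetic, sharing no code with the package implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def gotoh_local_score(a: str, b: str, match=2.0, mismatch=-1.0,
                      gap_open=-4.0, gap_extend=-1.0) -> float:
    """Affine-gap Smith-Waterman score by the three-matrix Gotoh recursion.

    gap of length k costs gap_open + (k-1)*gap_extend.
    """
    n, m = len(a), len(b)
    neg = -1e18
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)  # gap in a (left)
    f = np.full((n + 1, m + 1), neg)  # gap in b (up)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            e[i][j] = max(h[i][j - 1] + gap_open, e[i][j - 1] + gap_extend)
            f[i][j] = max(h[i - 1][j] + gap_open, f[i - 1][j] + gap_extend)
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def enumerate_global_alignments(a: str, b: str):
    """All global alignments of two short sequences as (aln_a, aln_b) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for x, y in enumerate_global_alignments(a[1:], b):
            yield a[0] + x, "-" + y
    if b:
        for x, y in enumerate_global_alignments(a, b[1:]):
            yield "-" + x, b[0] + y
    if a and b:
        for x, y in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + x, b[0] + y


def score_alignment(aln_a: str, aln_b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    score = 0.0
    for ca, cb in zip(aln_a, aln_b):
        if ca == "-" or cb == "-":
            score += gap
        elif ca == cb:
            score += match
        else:
            score += mismatch
    return score


def nw_best_alignments(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """(best score, all optimal global alignments).

    Independent recursion: the suffix-optimal score is memoized and every
    optimal path is enumerated from it.  For very short pairs this agrees
    with scoring all alignments of :func:`enumerate_global_alignments`
    (checked in the oracle's own test).
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        opts = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            opts.append(best(i + 1, j + 1) + s)
        if i < len(a):
            opts.append(best(i + 1, j) + gap)
        if j < len(b):
            opts.append(best(i, j + 1) + gap)
        return max(opts)

    def walk(i: int, j: int):
        if i == len(a) and j == len(b):
            yield "", ""
            return
        target = best(i, j)
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            if abs(best(i + 1, j + 1) + s - target) < 1e-9:
                for x, y in walk(i + 1, j + 1):
                    yield a[i] + x, b[j] + y
        if i < len(a) and abs(best(i + 1, j) + gap - target) < 1e-9:
            for x, y in walk(i + 1, j):
                yield a[i] + x, "-" + y
        if j < len(b) and abs(best(i, j + 1) + gap - target) < 1e-9:
            for x, y in walk(i, j + 1):
                yield "-" + x, b[j] + y

    return best(0, 0), list(walk(0, 0))


def alignment_identity(aln_a: str, aln_b: str) -> float:
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    return matches / len(aln_a)


def hypergeom_upper_tail(k_study: int, n_pop: int, k_pop: int, n_study: int) -> float:
    """P(X >= k_study) by exhaustive enumeration of all draws (n_pop <= 12)."""
    population = list(range(n_pop))
    annotated = set(range(k_pop))
    total = 0
    hits = 0
    for draw in combinations(population, n_study):
        total += 1
        if len(annotated.intersection(draw)) >= k_study:
            hits += 1
    return hits / total


def bh_step_up(p_values) -> np.ndarray:
    """Hand BH: q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def mann_whitney_exact_greater(x, y) -> tuple[float, float]:
    """(U of x, one-sided p) by enumeration of all group assignments."""
    pooled = list(x) + list(y)
    n_x = len(x)
    ranks = _rankdata(pooled)
    u_obs = sum(ranks[:n_x]) - n_x * (n_x + 1) / 2
    count = 0
    total = 0
    idx = range(len(pooled))
    for combo in combinations(idx, n_x):
        total += 1
        u = sum(ranks[i] for i in combo) - n_x * (n_x + 1) / 2
        if u >= u_obs - 1e-12:
            count += 1
    return u_obs, count / total


def _rankdata(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
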