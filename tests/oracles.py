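"""Independent brute-force oracles used to validate the implementation.

Everything here is written with explicit loops and no shared code with
the package, so agreement is evidence of correctness rather than
self-consistency.
"""

import itertools
import math

import numpy as np


def oracle_shortest_paths(weights):
    """All-pairs shortest paths on lengths 1/w via Floyd-Warshall loops."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    d = [[0.0 if i == j else (1.0 / w[i][j] if w[i][j] > 0 else math.inf)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def oracle_enumerated_shortest_paths(weights):
    """Exhaustive simple-path enumeration; only viable for tiny graphs."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    nodes = list(range(n))
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            best = math.inf
            for k in range(2, n + 1):
                for path in itertools.permutations(nodes, k):
                    if path[0] != src or path[-1] != dst:
                        continue
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if w[a][b] == 0:
                            ok = False
                            break
                        length += 1.0 / w[a][b]
                    if ok:
                        best = min(best, length)
            d[src, dst] = best
    return d


def oracle_strength(weights):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    return np.array([sum(w[i][j] for j in range(n) if j != i) for i in range(n)])


def oracle_closeness(weights):
    d = oracle_shortest_paths(weights)
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        reach = [d[i][j] for j in range(n) if j != i and math.isfinite(d[i][j])]
        if reach and sum(reach) > 0:
            out[i] = len(reach) / sum(reach)
    return out


def oracle_clustering(weights):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i][j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == h or j == i or h == i:
                    continue
                total += (w[i][j] * w[i][h] * w[j][h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def oracle_local_efficiency(weights):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if j != i and w[i][j] > 0]
        k = len(nb)
        if k < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        d = oracle_shortest_paths(sub)
        total = 0.0
        for a, j in enumerate(nb):
            for b, h in enumerate(nb):
                if j == h:
                    continue
                if math.isfinite(d[a][b]) and d[a][b] > 0:
                    total += (w[i][j] * w[i][h] / d[a][b]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def oracle_anova_2x2(cells):
    """Balanced 2x2 factorial sums of squares by direct enumeration.

    ``cells`` maps (a, b) in {0,1}^2 to a list of observations; returns
    (SS_A, SS_B, SS_AB, SS_within, df_within).
    """
    s = len(cells[(0, 0)])
    all_values = [y for v in cells.values() for y in v]
    grand = sum(all_values) / len(all_values)
    cell_mean = {k: sum(v) / len(v) for k, v in cells.items()}
    a_mean = {a: sum(cell_mean[(a, b)] for b in (0, 1)) / 2 for a in (0, 1)}
    b_mean = {b: sum(cell_mean[(a, b)] for a in (0, 1)) / 2 for b in (0, 1)}
    ss_a = sum(2 * s * (a_mean[a] - grand) ** 2 for a in (0, 1))
    ss_b = sum(2 * s * (b_mean[b] - grand) ** 2 for b in (0, 1))
    ss_ab = sum(
        s * (cell_mean[(a, b)] - a_mean[a] - b_mean[b] + grand) ** 2
        for a in (0, 1) for b in (0, 1)
    )
    ss_within = sum(
        (y - cell_mean[k]) ** 2 for k, v in cells.items() for y in v
    )
    return ss_a, ss_b, ss_ab, ss_within, 4 * (s - 1)


def oracle_ks_statistic(sample_a, sample_b):
    """Two-sample KS statistic: sup over pooled points of |ECDF_a - ECDF_b|."""
    a = sorted(sample_a)
    b = sorted(sample_b)
    pooled = sorted(set(a) | set(b))
    best = 0.0
    for x in pooled:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best
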