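"""Independently coded brute-force oracles used to cross-check the package.

Everything here is written from first principles (explicit normal equations,
Floyd-Warshall, exhaustive enumeration) and deliberately shares no code with
the implementation under test.
"""

from __future__ import annotations

import numpy as np


def gci_pair_bruteforce(x: np.ndarray, y: np.ndarray, p: int) -> tuple[float, float]:
    """Pairwise Granger causality indices via explicit normal equations.

    Returns (gci_x_to_y, gci_y_to_x), clamped at zero, using mean squared
    residuals from direct solves of X'X c = X'y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size

    def design(series_list):
        cols = []
        for s in series_list:
            for lag in range(1, p + 1):
                cols.append(s[p - lag : n - lag])
        return np.array(cols).T

    def mse(X, target):
        coef = np.linalg.solve(X.T @ X, X.T @ target)
        r = target - X @ coef
        return float(np.mean(r * r))

    Xx = design([x])
    Xy = design([y])
    Xxy = design([x, y])
    v_x_uni = mse(Xx, x[p:])
    v_y_uni = mse(Xy, y[p:])
    v_x_biv = mse(Xxy, x[p:])
    v_y_biv = mse(Xxy, y[p:])
    return (
        max(0.0, float(np.log(v_y_uni / v_y_biv))),
        max(0.0, float(np.log(v_x_uni / v_x_biv))),
    )


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs directed hop distances; np.inf for unreachable pairs."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj] = 1.0
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_and_unreachable(adj: np.ndarray) -> tuple[float, int]:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    unreachable = n * (n - 1) - len(vals)
    if not vals:
        return float("nan"), unreachable
    return float(np.mean(vals)), unreachable


def global_efficiency_bruteforce(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def degrees_bruteforce(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(in, out) degrees by explicit edge-list counting."""
    n = adj.shape[0]
    in_deg = np.zeros(n, int)
    out_deg = np.zeros(n, int)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                out_deg[i] += 1
                in_deg[j] += 1
    return in_deg, out_deg


def clustering_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Undirected clustering 2E/(k(k-1)) on the symmetrized graph by
    exhaustive neighbor-pair enumeration."""
    n = adj.shape[0]
    sym = adj | adj.T
    np.fill_diagonal(sym, False)
    ci = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if sym[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        e = 0
        for a in range(k):
            for b in range(a + 1, k):
                if sym[nbrs[a], nbrs[b]]:
                    e += 1
        ci[i] = 2 * e / (k * (k - 1))
    return ci


def select_threshold_scan(
    values: np.ndarray, grid: np.ndarray, max_isolated_fraction: float
) -> tuple[float, bool]:
    """Exhaustive grid scan of the integrity rule: evaluate every candidate,
    keep the largest feasible one; fall back to the smallest."""
    n = values.shape[0]
    best = None
    for thr in sorted(grid):
        adj = values > thr
        np.fill_diagonal(adj, False)
        total = adj.sum(0) + adj.sum(1)
        frac = np.mean(total == 0)
        if frac <= max_isolated_fraction:
            best = thr
    if best is None:
        return float(min(grid)), False
    return float(best), True
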