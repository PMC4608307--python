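"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: BC by explicit
shortest-path enumeration, the RCBD contrast by a generic design-matrix
least-squares solve, the hypergeometric tail by exact big-integer
combinatorics.
"""

from __future__ import annotations

from collections import deque
from math import comb

import numpy as np
from scipy import stats


def brute_force_bc(nodes: list, arcs: set[tuple]) -> dict:
    """Normalized betweenness by per-pair shortest-path enumeration."""
    n = len(nodes)
    succ = {v: [w for (u, w) in arcs if u == v] for v in nodes}
    raw = dict.fromkeys(nodes, 0.0)

    for s in nodes:
        # BFS distances from s
        dist = {s: 0}
        q = deque([s])
        while q:
            v = q.popleft()
            for w in succ[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    q.append(w)
        for t in nodes:
            if t == s or t not in dist:
                continue
            # enumerate every shortest s->t path explicitly (DFS over layers)
            paths = []
            stack = [(s, [s])]
            while stack:
                v, path = stack.pop()
                if v == t:
                    paths.append(path)
                    continue
                for w in succ[v]:
                    if w in dist and dist[w] == len(path) and dist[w] <= dist[t]:
                        stack.append((w, path + [w]))
            sigma = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                raw[v] += through / sigma
    if n < 3:
        return dict.fromkeys(nodes, 0.0)
    return {v: raw[v] / ((n - 1) * (n - 2)) for v in nodes}


def lstsq_rcbd(y: np.ndarray, pair_idx: tuple[int, int]):
    """Generic least-squares fit of the additive block+treatment model.

    ``y`` is a (b, k) cell table.  Returns (mse, df, estimate, t, p) for
    the cell-mean contrast between treatment columns ``pair_idx``.
    """
    b, k = y.shape
    rows, X = [], []
    for i in range(b):
        for j in range(k):
            x = np.zeros(1 + (b - 1) + (k - 1))
            x[0] = 1.0
            if i > 0:
                x[i] = 1.0  # donor dummies occupy columns 1..b-1
            if j > 0:
                x[b - 1 + j] = 1.0  # treatment dummies occupy the rest
            X.append(x)
            rows.append(y[i, j])
    X = np.array(X)
    yv = np.array(rows)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    df = b * k - X.shape[1]
    mse = resid @ resid / df

    j1, j2 = pair_idx
    c = np.zeros(X.shape[1])
    if j1 > 0:
        c[b - 1 + j1] = 1.0
    if j2 > 0:
        c[b - 1 + j2] = -1.0
    estimate = c @ beta
    cov = mse * np.linalg.inv(X.T @ X)
    se = np.sqrt(c @ cov @ c)
    t = estimate / se
    p = 2 * stats.t.sf(abs(t), df)
    return mse, df, estimate, t, p


def exact_hypergeom_upper_tail(k: int, N: int, K: int, n: int):
    """P(X >= k) by exact integer combinatorics (Fraction-precision)."""
    from fractions import Fraction

    total = comb(N, n)
    acc = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(acc, total)


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r^2 from raw sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxy = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    sxx = n * np.sum(x * x) - np.sum(x) ** 2
    syy = n * np.sum(y * y) - np.sum(y) ** 2
    return float(sxy**2 / (sxx * syy))
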