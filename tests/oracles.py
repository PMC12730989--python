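"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: Floyd-Warshall distances, exhaustive
triangle counting, textbook Pearson, and the raw exponential form of the
tanh mapping.  None of it shares code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), math.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def lp_eg_bruteforce(adj: np.ndarray) -> tuple[float, float]:
    """Characteristic path length (connected ordered pairs) and global
    efficiency (1/inf = 0) from Floyd-Warshall distances."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    inv_sum = 0.0
    finite = []
    n_pairs = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            n_pairs += 1
            if math.isfinite(d[i, j]):
                finite.append(d[i, j])
                inv_sum += 1.0 / d[i, j]
    eg = inv_sum / n_pairs
    lp = sum(finite) / len(finite) if finite else math.nan
    return lp, eg


def cp_eloc_bruteforce(adj: np.ndarray) -> tuple[float, float]:
    """Mean clustering (exhaustive triangle count) and local efficiency
    (brute-force efficiency of each neighbor subgraph)."""
    n = adj.shape[0]
    cs = []
    elocs = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            elocs.append(0.0)
            continue
        tri = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nb[a], nb[b]]:
                    tri += 1
        cs.append(2.0 * tri / (k * (k - 1)))
        sub = adj[np.ix_(nb, nb)]
        if sub.sum() == 0:
            elocs.append(0.0)
        else:
            _, eg_sub = lp_eg_bruteforce(sub)
            elocs.append(eg_sub)
    return float(np.mean(cs)), float(np.mean(elocs))


def pearson_hand(x, y) -> float:
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def tanh_exponential_form(esd: float) -> float:
    """R as the raw ratio (e^{2x} - 1) / (e^{2x} + 1)."""
    e = math.exp(2.0 * esd)
    return (e - 1.0) / (e + 1.0)


def random_graph(rng: np.random.Generator, n_max: int = 12) -> np.ndarray:
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.15, 0.8))
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T
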