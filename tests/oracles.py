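"""Independent reference implementations used only as test oracles.

These are deliberately written with different algorithms from the
production code: Floyd–Warshall (pure-Python triple loop) instead of
vectorized BFS, and a literal transcription of the Pearson formula
instead of ``np.corrcoef``.
"""

import math

import numpy as np

INF = math.inf


def floyd_warshall(adj) -> list[list[float]]:
    """All-pairs shortest paths by the classic dynamic program."""
    A = np.asarray(adj)
    n = A.shape[0]
    d = [[0.0 if i == j else (1.0 if A[i][j] else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == INF:
                continue
            for j in range(n):
                alt = dik + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return d


def ge_oracle(adj) -> float:
    """Global efficiency from Floyd–Warshall distances."""
    d = floyd_warshall(adj)
    n = len(d)
    if n < 2:
        raise ValueError("need >= 2 nodes")
    total = sum(1.0 / d[i][j]
                for i in range(n) for j in range(n)
                if i != j and d[i][j] != INF)
    return total / (n * (n - 1))


def le_oracle(adj) -> float:
    """Local efficiency by direct application of its definition."""
    A = np.asarray(adj)
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if A[i][j]]
        if len(nbrs) < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        total += ge_oracle(sub)
    return total / n


def pearson_bruteforce(x, y) -> float:
    """Sum((x-xbar)(y-ybar)) / (sx * sy * (n-1)) with sample SDs."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    sx = math.sqrt(sum((v - xbar) ** 2 for v in x) / (n - 1))
    sy = math.sqrt(sum((v - ybar) ** 2 for v in y) / (n - 1))
    num = sum((a - xbar) * (b - ybar) for a, b in zip(x, y))
    return num / (sx * sy * (n - 1))


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric hollow 0/1 adjacency with i.i.d. edges."""
    upper = rng.random((n, n)) < p
    A = np.triu(upper, 1)
    return (A | A.T).astype(np.uint8)
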