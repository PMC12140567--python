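"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over the defining
formulas, independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_loop(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r: covariance over the product of SDs."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sx = math.sqrt(sum((xi - mx) ** 2 for xi in x))
    sy = math.sqrt(sum((yi - my) ** 2 for yi in y))
    return cov / (sx * sy)


def correlation_matrix_loop(data: np.ndarray) -> np.ndarray:
    """Entry-by-entry correlation matrix with zero diagonal."""
    n_regions = data.shape[1]
    out = np.zeros((n_regions, n_regions))
    for i in range(n_regions):
        for j in range(n_regions):
            if i != j:
                out[i, j] = pearson_loop(data[:, i], data[:, j])
    return out


def degree_loop(adjacency: np.ndarray) -> np.ndarray:
    """Neighbor count per node by explicit iteration."""
    n = adjacency.shape[0]
    return np.array(
        [sum(1 for j in range(n) if j != i and adjacency[i, j] != 0) for i in range(n)],
        dtype=float,
    )


def mpc_loop(degrees: np.ndarray) -> np.ndarray:
    """Multiplex participation coefficient from an n x M degree matrix."""
    n, M = degrees.shape
    out = np.zeros(n)
    for i in range(n):
        o = sum(degrees[i])
        if o == 0:
            out[i] = 0.0
        else:
            out[i] = M / (M - 1) * (1 - sum((k / o) ** 2 for k in degrees[i]))
    return out


def bh_stepup_loop(pvals: list[float], q: float = 0.05) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg by the literal step-up definition.

    Adjusted p_(k) = min over j >= k of m * p_(j) / j, capped at 1;
    reject iff adjusted <= q.
    """
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj_sorted[rank - 1] = running
    adjusted = [0.0] * m
    for rank, i in enumerate(order):
        adjusted[i] = min(adj_sorted[rank], 1.0)
    return adjusted, [a <= q for a in adjusted]


def kruskal_from_expansion(counts: np.ndarray) -> float:
    """Tie-corrected H by expanding counts to per-subject ordinal scores."""
    from scipy import stats as sps

    groups = []
    for row in counts:
        values = []
        for cat, c in enumerate(row):
            values.extend([cat] * int(c))
        groups.append(values)
    return float(sps.kruskal(*groups).statistic)
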