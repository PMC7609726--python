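"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (triple-loop
TOM, agglomerative UPGMA by repeated matrix scanning, contingency-table
ARI) used to cross-check the vectorized library code.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from comira.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_expr(rng) -> ExpressionMatrix:
    """3 features x 5 samples, generic fixture."""
    data = pd.DataFrame(
        rng.standard_normal((3, 5)),
        index=["f1", "f2", "f3"],
        columns=[f"s{i}" for i in range(1, 6)],
    )
    return ExpressionMatrix(data)


# ---------------------------------------------------------------------------
# independent oracles


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Naive O(n^3) topological overlap with explicit loops."""
    a = a.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = 0.0
            for u in range(n):
                if u != i and u != j:
                    l += a[i, u] * a[u, j]
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r by the naive covariance formula."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / np.sqrt(vx * vy)


def upgma_oracle(d: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering, naive implementation.

    Clusters are merged greedily at the smallest average inter-cluster
    dissimilarity, tie broken by the smallest index pair.
    """
    d = d.astype(float)
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or avg < best[0] - 1e-15:
                    best = (avg, i, j)
        avg, i, j = best
        heights.append(avg)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def ari_oracle(labels_a, labels_b) -> float:
    """Adjusted Rand index from the contingency table."""
    a_ids = {x: i for i, x in enumerate(sorted(set(labels_a)))}
    b_ids = {x: i for i, x in enumerate(sorted(set(labels_b)))}
    c = np.zeros((len(a_ids), len(b_ids)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        c[a_ids[x], b_ids[y]] += 1
    n = c.sum()
    sum_ij = sum(comb(int(v), 2) for v in c.ravel())
    sum_i = sum(comb(int(v), 2) for v in c.sum(axis=1))
    sum_j = sum(comb(int(v), 2) for v in c.sum(axis=0))
    expected = sum_i * sum_j / comb(n, 2)
    max_index = (sum_i + sum_j) / 2.0
    return (sum_ij - expected) / (max_index - expected)


def km_oracle(time, event):
    """Brute-force product-limit: product over distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    grid = np.unique(time[event])
    surv = {}
    s = 1.0
    for t in grid:
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & event).sum())
        s *= 1.0 - d / n_at_risk
        surv[float(t)] = s
    return surv
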