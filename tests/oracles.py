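"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths they check: naive O(n^3) UPGMA with
recomputed cross-cluster means, exact signed-rank p by enumerating all sign
assignments, and a literal transcription of the Benjamini-Hochberg step-up
formula.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def naive_upgma(d: np.ndarray):
    """UPGMA by exhaustive recomputation.

    Returns (heights, partitions) where ``partitions[k]`` is the set of
    frozenset clusters (over leaf indices) present when exactly k clusters
    remain, for k = n .. 1.
    """
    n = d.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    heights: list[float] = []
    partitions: dict[int, set[frozenset[int]]] = {n: set(clusters)}
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            pairs = [(a, b) for a in clusters[i] for b in clusters[j]]
            h = float(np.mean([d[a, b] for a, b in pairs]))
            if best is None or h < best[0]:
                best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] | clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
        partitions[len(clusters)] = set(clusters)
    return heights, partitions


def signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors."""
    x = np.asarray(diffs, dtype=float)
    x = x[x != 0]
    n = x.size
    ranks = rankdata(np.abs(x))
    w_obs = float(ranks[x > 0].sum())
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(sum(r for s, r in zip(signs, ranks) if s)))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Literal BH: sort ascending, adj_(i) = min_{j>=i} m*p_(j)/j, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def euclidean_brute(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y))))
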