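"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: shortest paths are found
by exhaustive simple-path enumeration, the signed-rank distribution by
iterating over every sign assignment, and the small-sample mean resultant
length by direct Monte-Carlo simulation.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_shortest_path(lengths: np.ndarray, j: int, h: int) -> float:
    """Exhaustive min over all simple paths from j to h (lengths: 0 = no edge)."""
    n = lengths.shape[0]
    others = [k for k in range(n) if k not in (j, h)]
    best = np.inf
    for r in range(len(others) + 1):
        for mids in itertools.permutations(others, r):
            path = (j, *mids, h)
            total = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if lengths[a, b] == 0:
                    ok = False
                    break
                total += lengths[a, b]
            if ok:
                best = min(best, total)
    return best


def brute_local_efficiency(weights: np.ndarray) -> np.ndarray:
    """Weighted local efficiency by exhaustive neighbor-subgraph enumeration."""
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        lengths = np.zeros_like(sub)
        np.divide(1.0, sub, out=lengths, where=sub > 0)
        total = 0.0
        for a, j in enumerate(nbrs):
            for b, h in enumerate(nbrs):
                if a == b:
                    continue
                d = brute_shortest_path(lengths, a, b)
                if np.isfinite(d) and d > 0:
                    total += (weights[i, j] * weights[i, h] / d) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def brute_degree(weights: np.ndarray) -> np.ndarray:
    return (np.asarray(weights) > 0).sum(axis=1)


def brute_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by iterating over all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def random_weighted_graph(rng: np.random.Generator, n: int,
                          edge_prob: float = 0.6) -> np.ndarray:
    """Random symmetric weighted graph with weights in (0, 1], zero diagonal."""
    w = rng.random((n, n))
    mask = rng.random((n, n)) < edge_prob
    w = np.triu(w * mask, k=1)
    return w + w.T
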