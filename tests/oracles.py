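"""Independent brute-force oracles for the rank-invariant statistics.

Each oracle works directly on the list of subject-level (x, y) pairs by
exhaustive enumeration, never through the closed-form marginal/cumulative
expressions used by the implementation.
"""
from __future__ import annotations

import numpy as np


def pa_oracle(pairs: list[tuple[int, int]], k: int = 0) -> float:
    """Direct pair counting: percent of pairs within k categories."""
    hits = sum(1 for x, y in pairs if abs(x - y) <= k)
    return 100.0 * hits / len(pairs)


def rp_oracle(pairs: list[tuple[int, int]]) -> float:
    """Exhaustive n^2 enumeration of independent marginal draws:
    P(Y > X) - P(Y < X)."""
    n = len(pairs)
    total = 0
    for x, _ in pairs:
        for _, y in pairs:
            total += (y > x) - (y < x)
    return total / n**2


def rc_oracle(pairs: list[tuple[int, int]]) -> float:
    """Exhaustive n^3 triple enumeration: probability that a Y value lies
    strictly between two independent X values, minus the converse."""
    xs = [x for x, _ in pairs]
    ys = [y for _, y in pairs]
    n = len(pairs)
    total = 0
    for y in ys:
        for x1 in xs:
            for x2 in xs:
                total += (min(x1, x2) < y < max(x1, x2))
    for x in xs:
        for y1 in ys:
            for y2 in ys:
                total -= (min(y1, y2) < x < max(y1, y2))
    return total / n**3


def _augmented_ranks(keys: list[tuple[int, int]]) -> np.ndarray:
    """Mean ranks after sorting by key, equal keys sharing the mean rank."""
    order = sorted(range(len(keys)), key=lambda s: keys[s])
    ranks = np.empty(len(keys), dtype=float)
    pos = 0
    while pos < len(order):
        end = pos
        while end < len(order) and keys[order[end]] == keys[order[pos]]:
            end += 1
        mean_rank = (pos + 1 + end) / 2.0  # mean of positions pos+1 .. end
        for s in order[pos:end]:
            ranks[s] = mean_rank
        pos = end
    return ranks


def rank_oracle(pairs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level augmented mean ranks: sort by own category, break ties
    by the paired assessment's category, tied subjects share the mean rank."""
    r1 = _augmented_ranks([(x, y) for x, y in pairs])
    r2 = _augmented_ranks([(y, x) for x, y in pairs])
    return r1, r2


def rv_oracle(pairs: list[tuple[int, int]]) -> float:
    """RV from subject-level augmented ranks."""
    r1, r2 = rank_oracle(pairs)
    n = len(pairs)
    return 6.0 * float(((r1 - r2) ** 2).sum()) / n**3


def random_table(rng: np.random.Generator, max_C: int = 5,
                 max_n: int = 12) -> np.ndarray:
    """A random small contingency table (at least one count)."""
    C = int(rng.integers(1, max_C + 1))
    n = int(rng.integers(1, max_n + 1))
    cells = rng.integers(0, C * C, size=n)
    return np.bincount(cells, minlength=C * C).reshape(C, C)


def table_pairs(counts: np.ndarray) -> list[tuple[int, int]]:
    out = []
    C = counts.shape[0]
    for i in range(C):
        for j in range(C):
            out.extend([(i, j)] * int(counts[i, j]))
    return out
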