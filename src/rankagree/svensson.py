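"""Rank-invariant agreement statistics for paired ordinal classifications.

Given a C x C contingency table of paired ordinal assessments (cell counts
n_ij, row marginals a_i from the first assessment, column marginals b_j from
the second), this module computes the Svensson family of measures:

* **PA** — percentage agreement, optionally within a tolerance of k
  categories: ``100 * sum_{|i-j|<=k} n_ij / n``.
* **RP** — relative position, the systematic shift between the two marginal
  distributions: ``P(Y > X) - P(Y < X)`` for X, Y drawn independently from
  the row and column marginals.  RP > 0 means the second assessment used
  higher categories more often.
* **RC** — relative concentration: the probability that a second-assessment
  value lies strictly between two independent first-assessment values, minus
  the converse.  RC > 0 means the second assessment is more concentrated
  towards the central categories.
* **RV** — relative rank variance, the random (individual) component of
  disagreement that remains after the systematic components: based on the
  squared differences of each pair's *augmented mean ranks*, where subjects
  are ranked by their own category with ties broken by the paired
  assessment's category, tied subjects sharing the mean rank.
* **ROC-style marginal curve** — the two cumulative marginal distributions
  plotted against each other; bowing off the diagonal indicates a shift in
  position, an S-shape a difference in concentration.

All statistics are rank-invariant: they depend only on the ordering of
categories, never on numeric codes, which is what makes them appropriate for
ordinal instruments such as the Fugl-Meyer scales.

Batch variants (``*_batch``) operate on stacks of tables with shape
(..., C, C); the bootstrap machinery in :mod:`rankagree.inference` relies on
them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .errors import ValidationError
from .pairing import ContingencyTable

TableLike = Union[ContingencyTable, np.ndarray, Sequence[Sequence[int]]]


def _counts(table: TableLike) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


# ---------------------------------------------------------------------------
# batch kernels (tables: float/int array, shape (..., C, C))


def pa_batch(tables: np.ndarray, k: int = 0) -> np.ndarray:
    tables = np.asarray(tables, dtype=float)
    C = tables.shape[-1]
    idx = np.arange(C)
    mask = np.abs(idx[:, None] - idx[None, :]) <= k
    n = tables.sum(axis=(-2, -1))
    return 100.0 * tables[..., mask].sum(axis=-1) / n


def rp_batch(tables: np.ndarray) -> np.ndarray:
    tables = np.asarray(tables, dtype=float)
    a = tables.sum(axis=-1)
    b = tables.sum(axis=-2)
    n = a.sum(axis=-1)
    A = np.cumsum(a, axis=-1)
    a_lt = A - a                      # sum_{p<c} a_p
    a_gt = n[..., None] - A           # sum_{p>c} a_p
    p_gt = (b * a_lt).sum(axis=-1)    # n^2 * P(Y > X)
    p_lt = (b * a_gt).sum(axis=-1)    # n^2 * P(Y < X)
    return (p_gt - p_lt) / n**2


def rc_batch(tables: np.ndarray) -> np.ndarray:
    tables = np.asarray(tables, dtype=float)
    a = tables.sum(axis=-1)
    b = tables.sum(axis=-2)
    n = a.sum(axis=-1)
    A = np.cumsum(a, axis=-1)
    B = np.cumsum(b, axis=-1)
    a_lt, a_gt = A - a, n[..., None] - A
    b_lt, b_gt = B - b, n[..., None] - B
    term_y_between = (b * a_lt * a_gt).sum(axis=-1)
    term_x_between = (a * b_lt * b_gt).sum(axis=-1)
    return 2.0 * (term_y_between - term_x_between) / n**3


def rv_batch(tables: np.ndarray) -> np.ndarray:
    tables = np.asarray(tables, dtype=float)
    a = tables.sum(axis=-1)
    b = tables.sum(axis=-2)
    n = a.sum(axis=-1)
    a_lt = np.cumsum(a, axis=-1) - a          # per row i
    b_lt = np.cumsum(b, axis=-1) - b          # per column j
    row_excl = np.cumsum(tables, axis=-1) - tables  # sum_{q<j} n_iq
    col_excl = np.cumsum(tables, axis=-2) - tables  # sum_{p<i} n_pj
    # the shared within-cell term (n_ij + 1)/2 cancels in the difference
    r1 = a_lt[..., :, None] + row_excl
    r2 = b_lt[..., None, :] + col_excl
    return 6.0 * (tables * (r1 - r2) ** 2).sum(axis=(-2, -1)) / n**3


# ---------------------------------------------------------------------------
# public single-table API


def percentage_agreement(table: TableLike, k: int = 0) -> float:
    """Percentage of pairs within ``k`` categories of each other (k=0: exact)."""
    if k < 0:
        raise ValidationError("tolerance k must be a nonnegative integer")
    return float(pa_batch(_counts(table)[None], k=int(k))[0])


def min_tolerance(table: TableLike, threshold_percent: float = 70.0) -> int:
    """Smallest tolerance k whose PA_k reaches the threshold (default 70%).

    Always terminates with k <= C-1, where PA is 100 by construction.
    """
    if not 0 < threshold_percent <= 100:
        raise ValidationError("threshold_percent must lie in (0, 100]")
    counts = _counts(table)
    for k in range(counts.shape[0]):
        if percentage_agreement(counts, k) >= threshold_percent:
            return k
    return counts.shape[0] - 1  # unreachable; PA_{C-1} == 100


def relative_position(table: TableLike) -> float:
    """Systematic position shift RP = P(Y > X) - P(Y < X), in [-1, 1]."""
    return float(rp_batch(_counts(table)[None])[0])


def relative_position_from_marginals(p: Sequence[float], q: Sequence[float]) -> float:
    """RP for two category distributions (probability vectors) directly."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("marginal vectors must have equal length")
    P = np.cumsum(p)
    p_lt = P - p
    p_gt = 1.0 - P
    return float((q * p_lt).sum() - (q * p_gt).sum())


def relative_concentration(table: TableLike) -> float:
    """Relative concentration RC (triple-based contrast, see module docstring).

    Uses the unordered-extreme-pair convention (normalisation 2/n^3); the
    attainable extreme is then +-0.5, reached when one assessment puts all
    mass centrally and the other splits it evenly over the two extremes.
    """
    return float(rc_batch(_counts(table)[None])[0])


@dataclass(frozen=True)
class AugmentedRankTable:
    """Augmented mean ranks per nonempty cell.

    ``r1[i, j]``/``r2[i, j]`` are the mean ranks of cell (i, j)'s subjects
    under the first/second assessment's ordering (own category first, the
    paired category breaking ties, cell members sharing the mean rank).
    Entries of empty cells are NaN.
    """

    r1: np.ndarray
    r2: np.ndarray
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def augmented_mean_ranks(table: TableLike) -> AugmentedRankTable:
    """Augmented mean ranks R1_ij, R2_ij of every nonempty cell."""
    counts = _counts(table)
    t = counts.astype(float)
    a = t.sum(axis=1)
    b = t.sum(axis=0)
    a_lt = np.cumsum(a) - a
    b_lt = np.cumsum(b) - b
    row_excl = np.cumsum(t, axis=1) - t
    col_excl = np.cumsum(t, axis=0) - t
    half = (t + 1.0) / 2.0
    r1 = a_lt[:, None] + row_excl + half
    r2 = b_lt[None, :] + col_excl + half
    empty = counts == 0
    r1[empty] = np.nan
    r2[empty] = np.nan
    return AugmentedRankTable(r1=r1, r2=r2, counts=counts)


def relative_rank_variance(table: TableLike) -> float:
    """Random-disagreement measure RV = (6/n^3) * sum n_ij (R1_ij - R2_ij)^2.

    Zero for any diagonal table; approaches 1 when the two assessments are
    independent.
    """
    return float(rv_batch(_counts(table)[None])[0])


@dataclass(frozen=True)
class RocCurve:
    """Cumulative-marginal agreement curve.

    Points (u_c, v_c) = (A_{<=c}/n, B_{<=c}/n) for c = -1 .. C-1; identical
    marginals put every point on the diagonal, a position shift bows the
    curve to one side, a concentration difference makes it S-shaped.
    """

    points: tuple[tuple[float, float], ...]

    @property
    def u(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def v(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def roc_points(table: TableLike) -> RocCurve:
    """ROC-style curve of the two cumulative marginal distributions."""
    counts = _counts(table)
    n = counts.sum()
    u = np.concatenate([[0.0], np.cumsum(counts.sum(axis=1)) / n])
    v = np.concatenate([[0.0], np.cumsum(counts.sum(axis=0)) / n])
    return RocCurve(points=tuple(zip(u.tolist(), v.tolist())))


@dataclass(frozen=True)
class AgreementEstimates:
    """Point estimates of all agreement measures for one table."""

    PA: float
    pa_k: dict[int, float] = field(default_factory=dict)
    min_k: int = 0
    RP: float = 0.0
    RC: float = 0.0
    RV: float = 0.0


def agreement_estimates(table: TableLike, tolerances: Sequence[int] = (),
                        threshold_percent: float = 70.0) -> AgreementEstimates:
    """All point estimates for one contingency table in a single call."""
    counts = _counts(table)
    return AgreementEstimates(
        PA=percentage_agreement(counts, 0),
        pa_k={int(k): percentage_agreement(counts, int(k)) for k in tolerances},
        min_k=min_tolerance(counts, threshold_percent),
        RP=relative_position(counts),
        RC=relative_concentration(counts),
        RV=relative_rank_variance(counts),
    )
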