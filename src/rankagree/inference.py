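"""Uncertainty quantification and disagreement classification.

Confidence intervals for the rank-invariant measures are obtained by a
nonparametric percentile bootstrap over subjects: pairs are resampled with
replacement (equivalently, a multinomial redraw of the contingency-table
cells), the statistic is recomputed on each resample, and the interval is
the central quantile range of the bootstrap distribution.  The bootstrap
makes no distributional assumption, which suits rank statistics on small
ordinal tables.

Classification follows the conventional reading of the measures against a
+-0.1 negligibility band:

* ``significant`` — |estimate| >= 0.1 and the CI excludes 0;
* ``tendency`` — |estimate| >= 0.1 but the CI still includes 0;
* ``negligible_significant`` — |estimate| < 0.1 yet the CI excludes 0
  (statistically detectable but clinically negligible);
* ``none`` — otherwise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np

from .errors import ValidationError
from .pairing import ContingencyTable, PairedOrdinalSample, build_contingency
from . import svensson

_BATCH_STATS = {
    "PA": svensson.pa_batch,
    "RP": svensson.rp_batch,
    "RC": svensson.rc_batch,
    "RV": svensson.rv_batch,
}

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with its percentile-bootstrap confidence interval."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    B: int = 2000
    seed: Optional[int] = None
    statistic: str = ""

    def contains_zero(self) -> bool:
        return self.lower <= 0.0 <= self.upper


class DisagreementFlag(str, Enum):
    NONE = "none"
    NEGLIGIBLE_SIGNIFICANT = "negligible_significant"
    TENDENCY = "tendency"
    SIGNIFICANT = "significant"


def _resolve_table(sample: Union[PairedOrdinalSample, ContingencyTable]) -> ContingencyTable:
    if isinstance(sample, PairedOrdinalSample):
        return build_contingency(sample)
    if isinstance(sample, ContingencyTable):
        return sample
    return ContingencyTable(np.asarray(sample))


def bootstrap_ci(sample: Union[PairedOrdinalSample, ContingencyTable],
                 statistic: str,
                 B: int = 2000,
                 level: float = 0.95,
                 seed: SeedLike = None,
                 tolerance: int = 0) -> IntervalEstimate:
    """Percentile-bootstrap CI for PA/RP/RC/RV, resampling subjects.

    Because every statistic depends on the data only through the contingency
    table, resampling n subject pairs with replacement is carried out as a
    single multinomial redraw over the table's nonempty cells, which keeps
    B = 2000 replicates cheap even at sum-score resolution.  A fixed ``seed``
    makes the interval bit-reproducible.
    """
    if B < 100:
        raise ValidationError("bootstrap needs B >= 100 resamples")
    if not 0 < level < 1:
        raise ValidationError("confidence level must lie strictly in (0, 1)")
    stat_key = statistic.upper()
    if stat_key not in _BATCH_STATS:
        raise ValidationError(
            f"unknown statistic '{statistic}' (choose from {sorted(_BATCH_STATS)})"
        )
    table = _resolve_table(sample)
    counts = table.counts
    C, n = table.C, table.n

    kwargs = {"k": int(tolerance)} if stat_key == "PA" else {}
    func = _BATCH_STATS[stat_key]
    estimate = float(func(counts[None].astype(float), **kwargs)[0])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = counts.ravel()
    nz = np.flatnonzero(flat)
    probs = flat[nz] / n
    draws = rng.multinomial(n, probs, size=B)
    boot = np.zeros((B, C * C), dtype=float)
    boot[:, nz] = draws
    stats = func(boot.reshape(B, C, C), **kwargs)

    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, [alpha, 1.0 - alpha])
    return IntervalEstimate(
        estimate=estimate,
        lower=float(lower),
        upper=float(upper),
        level=level,
        B=B,
        seed=seed if isinstance(seed, int) else None,
        statistic=stat_key,
    )


def classify(est: IntervalEstimate, band: float = 0.1) -> DisagreementFlag:
    """Classify a measure against the negligibility band and its CI.

    The four outcomes are exhaustive and mutually exclusive; see the module
    docstring for their reading.
    """
    if not est.lower <= est.upper:
        raise ValidationError("invalid interval: lower > upper")
    nonneg = abs(est.estimate) >= band
    zero_out = not est.contains_zero()
    if nonneg and zero_out:
        return DisagreementFlag.SIGNIFICANT
    if nonneg:
        return DisagreementFlag.TENDENCY
    if zero_out:
        return DisagreementFlag.NEGLIGIBLE_SIGNIFICANT
    return DisagreementFlag.NONE


def display_value(x: float) -> str:
    """Format a measure for tables: values with |x| <= 0.01 collapse to "0",
    everything else prints with two decimals."""
    if not math.isfinite(x):
        raise ValidationError(f"cannot display non-finite value {x!r}")
    if abs(x) <= 0.01:
        return "0"
    return f"{x:.2f}"
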