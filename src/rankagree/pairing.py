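"""Paired-sample extraction: from long-format ratings to C x C contingency tables.

A reliability study yields two families of comparisons:

* **intra-rater** — one rater's first-occasion vs second-occasion scores,
  over the subjects that rater assessed (row = occasion 1, column = occasion 2);
* **inter-rater** — the two paired raters' scores at one occasion, pooled
  over all subjects (row = first-listed rater of each pair).

Each comparison, at a single item or at a sum-score level, gives a
:class:`PairedOrdinalSample` (one (x, y) pair per subject) and from it a
:class:`ContingencyTable` of cell counts n_ij with row marginals a_i and
column marginals b_j — the substrate of all rank-invariant statistics.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .scale import OrdinalScale, RatingsDataset, sum_scores

logger = logging.getLogger(__name__)

Pairing = Mapping[str, tuple[str, str]]


@dataclass(frozen=True)
class ComparisonSpec:
    """One paired comparison.

    ``first``/``second`` are (rater_id, occasion) coordinates; for an inter
    comparison the rater_id slots are ``None`` and the per-subject rater pair
    comes from ``pairing`` (first-listed rater supplies x).  ``unit`` names
    the item or sum group to compare (may be filled in later with
    :func:`dataclasses.replace`).
    """

    mode: str  # "intra" | "inter"
    first: tuple[Optional[str], int]
    second: tuple[Optional[str], int]
    unit: Optional[str] = None
    label: str = ""
    pairing: Optional[Pairing] = None

    def __post_init__(self) -> None:
        if self.mode not in ("intra", "inter"):
            raise ValidationError(f"unknown comparison mode '{self.mode}'")
        if self.mode == "intra":
            if self.first[0] != self.second[0] or self.first[0] is None:
                raise ValidationError("intra comparison requires one fixed rater")
            if self.first[1] == self.second[1]:
                raise ValidationError("intra comparison requires two distinct occasions")
        else:
            if self.first[1] != self.second[1]:
                raise ValidationError("inter comparison requires a single occasion")
            fixed = self.first[0] is not None and self.second[0] is not None
            if fixed and self.first[0] == self.second[0]:
                raise ValidationError("inter comparison requires two distinct raters")
            if not fixed and self.pairing is None:
                raise ValidationError(
                    "inter comparison with unspecified raters needs a pairing map"
                )
        if not self.label:
            object.__setattr__(self, "label", _default_label(self))


def _default_label(spec: "ComparisonSpec") -> str:
    if spec.mode == "intra":
        return f"intra:{spec.first[0]}"
    return f"inter:occ{spec.first[1]}"


@dataclass(frozen=True)
class PairedOrdinalSample:
    """Per-subject paired levels for one comparison.

    Levels are zero-based internally (0 .. C-1); ``offset`` restores the
    original score scale (score = level + offset).
    """

    x: np.ndarray
    y: np.ndarray
    C: int
    subject_ids: tuple[str, ...]
    offset: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=int)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValidationError("x and y must be 1-d arrays of equal length")
        if x.size == 0:
            raise ValidationError("paired sample is empty")
        if self.C < 1:
            raise ValidationError("C must be a positive integer")
        for arr, name in ((x, "x"), (y, "y")):
            if arr.min() < 0 or arr.max() >= self.C:
                raise ValidationError(f"{name} levels outside [0, {self.C - 1}]")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.x.tolist(), self.y.tolist()))


@dataclass(frozen=True)
class ContingencyTable:
    """C x C paired-classification counts (rows: first assessment)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError("contingency table must be square")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValidationError("contingency counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("contingency counts must be nonnegative")
        if counts.sum() < 1:
            raise ValidationError("contingency table must contain at least one pair")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_pairs(cls, x: Sequence[int], y: Sequence[int], C: int) -> "ContingencyTable":
        x = np.asarray(x, dtype=int)
        y = np.asarray(y, dtype=int)
        flat = np.bincount(x * C + y, minlength=C * C)
        return cls(flat.reshape(C, C))

    @property
    def C(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def a(self) -> np.ndarray:
        """Row marginals (first assessment)."""
        return self.counts.sum(axis=1)

    @property
    def b(self) -> np.ndarray:
        """Column marginals (second assessment)."""
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy())

    def to_pairs(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for i in range(self.C):
            for j in range(self.C):
                out.extend([(i, j)] * int(self.counts[i, j]))
        return out


# ---------------------------------------------------------------------------
# study design


def load_design(source: Union[str, Path, Mapping, None]) -> dict:
    """Parse a study-design config: ``occasions`` list and ``pairing``
    (explicit subject -> [rater, rater] map, or ``"infer"``)."""
    if source is None:
        return {"occasions": None, "pairing": "infer"}
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ValidationError(f"design file '{source}' does not exist")
        cfg = yaml.safe_load(path.read_text()) or {}
        if not isinstance(cfg, Mapping):
            raise ValidationError(f"design config {path} does not parse to a mapping")
        cfg = dict(cfg)
    occasions = cfg.get("occasions")
    if occasions is not None:
        occasions = [int(o) for o in occasions]
    pairing = cfg.get("pairing", "infer")
    if pairing != "infer":
        pairing = {str(s): tuple(str(r) for r in rs) for s, rs in pairing.items()}
        for s, rs in pairing.items():
            if len(rs) != 2 or rs[0] == rs[1]:
                raise ValidationError(
                    f"pairing for subject '{s}' must list two distinct raters"
                )
    return {"occasions": occasions, "pairing": pairing}


def infer_pairing(data: RatingsDataset) -> Pairing:
    """Derive the subject -> (rater, rater) map from the data.

    Requires every subject to have been scored by exactly two raters
    (the pairwise design); rater order within a pair is lexicographic.
    """
    pairing: dict[str, tuple[str, str]] = {}
    for subject, grp in data.df.groupby("subject_id", sort=True):
        raters = sorted(grp["rater_id"].unique())
        if len(raters) != 2:
            raise ValidationError(
                f"subject '{subject}' was scored by {len(raters)} rater(s) "
                f"({raters}); the pairwise design requires exactly 2"
            )
        pairing[str(subject)] = (raters[0], raters[1])
    return pairing


def enumerate_comparisons(
    data: RatingsDataset,
    design: Union[str, Path, Mapping, None] = None,
    modes: Union[str, Sequence[str]] = "auto",
) -> list[ComparisonSpec]:
    """List the comparisons a pairwise two-occasion design supports.

    Intra-rater: one spec per rater (occasion 1 vs occasion 2 within rater).
    Inter-rater: one spec per occasion, pooling each subject's rater pair.
    With ``modes="auto"`` a mode that the data cannot support (a single
    occasion, or a single rater) is silently skipped; naming modes
    explicitly turns that into an error.
    """
    cfg = load_design(design)
    occasions = cfg["occasions"] or data.occasions
    raters = data.raters

    auto = modes == "auto"
    wanted = ("intra", "inter") if auto else tuple(modes)
    for m in wanted:
        if m not in ("intra", "inter"):
            raise ValidationError(f"unknown comparison mode '{m}'")

    specs: list[ComparisonSpec] = []

    if "intra" in wanted:
        if len(occasions) < 2:
            if not auto:
                raise ValidationError(
                    "intra-rater comparisons require at least two occasions"
                )
        else:
            o1, o2 = occasions[0], occasions[1]
            for r in raters:
                specs.append(ComparisonSpec(
                    mode="intra", first=(r, o1), second=(r, o2),
                ))

    if "inter" in wanted:
        if len(raters) < 2:
            if not auto:
                raise ValidationError(
                    "inter-rater comparisons require at least two raters"
                )
        else:
            pairing = cfg["pairing"]
            if pairing == "infer":
                pairing = infer_pairing(data)
            for occ in occasions:
                specs.append(ComparisonSpec(
                    mode="inter", first=(None, occ), second=(None, occ),
                    pairing=pairing,
                ))
    return specs


# ---------------------------------------------------------------------------
# pair extraction


def _unit_values(data: RatingsDataset, scale: OrdinalScale,
                 unit: str) -> tuple[pd.DataFrame, int, int]:
    """Per-assessment values for a unit; returns (frame, offset, C)."""
    if unit in scale.sum_groups:
        values = sum_scores(data, scale, unit)
        gmin, gmax = scale.group_range(unit)
        return values, gmin, gmax - gmin + 1
    if unit in scale.item_ids:
        item = scale.item(unit)
        values = data.df.loc[data.df["item_id"] == unit,
                             ["subject_id", "rater_id", "occasion", "score"]]
        return values.copy(), item.min_level, item.n_levels
    raise ValidationError(
        f"unit '{unit}' is neither an item nor a sum group of scale '{scale.name}'"
    )


def extract_pairs(data: RatingsDataset, scale: OrdinalScale,
                  spec: ComparisonSpec) -> PairedOrdinalSample:
    """Build the paired sample for one comparison.

    Subjects missing either side of the comparison are dropped with a
    warning; an error is raised only when no usable subject remains.
    """
    if spec.unit is None:
        raise ValidationError("ComparisonSpec.unit must be set before extraction")
    values, offset, C = _unit_values(data, scale, spec.unit)

    if spec.mode == "intra":
        rater = spec.first[0]
        sub = values[values["rater_id"] == rater]
        wide = sub.pivot_table(index="subject_id", columns="occasion",
                               values="score", aggfunc="first")
        for occ in (spec.first[1], spec.second[1]):
            if occ not in wide.columns:
                wide[occ] = np.nan
        wide = wide[[spec.first[1], spec.second[1]]]
    else:
        occ = spec.first[1]
        sub = values[values["occasion"] == occ]
        lookup = sub.set_index(["subject_id", "rater_id"])["score"]
        pairing = spec.pairing if spec.pairing is not None else infer_pairing(data)
        if spec.first[0] is not None:
            pairing = {s: (spec.first[0], spec.second[0])
                       for s in sub["subject_id"].unique()}
        rows = {}
        for subject in sorted(set(sub["subject_id"])):
            pair = pairing.get(str(subject))
            if pair is None:
                logger.warning("extract_pairs[%s/%s]: subject '%s' missing from "
                               "pairing map; dropped", spec.label, spec.unit, subject)
                continue
            r1, r2 = pair
            rows[subject] = (lookup.get((subject, r1), np.nan),
                             lookup.get((subject, r2), np.nan))
        wide = pd.DataFrame.from_dict(rows, orient="index", columns=["x", "y"])
        wide = wide.sort_index()

    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        logger.warning(
            "extract_pairs[%s/%s]: dropped %d subject(s) missing one side: %s",
            spec.label, spec.unit, len(dropped), dropped,
        )
    if complete.empty:
        raise ValidationError(
            f"comparison {spec.label} on unit '{spec.unit}' has no usable subject"
        )
    x = complete.iloc[:, 0].astype(int).to_numpy() - offset
    y = complete.iloc[:, 1].astype(int).to_numpy() - offset
    return PairedOrdinalSample(
        x=x, y=y, C=C,
        subject_ids=tuple(str(s) for s in complete.index),
        offset=offset,
        label=f"{spec.label}/{spec.unit}",
    )


def build_contingency(sample: PairedOrdinalSample) -> ContingencyTable:
    """Tally a paired sample into its C x C contingency table."""
    return ContingencyTable.from_pairs(sample.x, sample.y, sample.C)
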