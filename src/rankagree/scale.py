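"""Ordinal rating instruments, rating-data validation, sum scores, floor/ceiling.

An :class:`OrdinalScale` describes an instrument as an ordered list of items,
each scored on a small integer range, plus named sum-score groups.  The
built-in ``"fma_le"`` scale is the lower-extremity motor domain of the
Fugl-Meyer assessment: 17 items scored 0 (none) / 1 (partial) / 2 (full),
with the conventional sum scores SUM E II/III/IV, SUM E, SUM F and the
0-34 total.

Rating data are long-format records, one row per
(subject, rater, occasion, item) with an integer score.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "rater_id", "occasion", "item_id", "score")
KEY_COLUMNS = ("subject_id", "rater_id", "occasion", "item_id")


@dataclass(frozen=True)
class ItemDefinition:
    """One item of an ordinal instrument.

    ``min_level``/``max_level`` bound the admissible integer scores;
    ``section`` is a free grouping label (e.g. ``"E.II"`` for the FMA-LE).
    """

    item_id: str
    label: str = ""
    section: str = ""
    min_level: int = 0
    max_level: int = 2

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be a non-empty string")
        if self.min_level >= self.max_level:
            raise ValidationError(
                f"item '{self.item_id}': min_level ({self.min_level}) must be "
                f"strictly below max_level ({self.max_level})"
            )

    @property
    def n_levels(self) -> int:
        return self.max_level - self.min_level + 1


@dataclass(frozen=True)
class OrdinalScale:
    """An ordinal instrument: ordered items plus named sum-score groups."""

    name: str
    items: tuple[ItemDefinition, ...]
    sum_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if not ids:
            raise ValidationError(f"scale '{self.name}' has no items")
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(
                f"scale '{self.name}': duplicate item_id(s) {sorted(dup)}"
            )
        for group, members in self.sum_groups.items():
            unknown = [m for m in members if m not in ids]
            if unknown:
                raise ValidationError(
                    f"sum_group '{group}' references unknown item(s) {unknown}"
                )
            if not members:
                raise ValidationError(f"sum_group '{group}' is empty")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise ValidationError(f"unknown item_id '{item_id}' in scale '{self.name}'")

    def group_items(self, group: str) -> tuple[ItemDefinition, ...]:
        if group not in self.sum_groups:
            raise ValidationError(
                f"unknown sum group '{group}' in scale '{self.name}' "
                f"(available: {sorted(self.sum_groups)})"
            )
        return tuple(self.item(i) for i in self.sum_groups[group])

    def group_range(self, group: str) -> tuple[int, int]:
        """(min, max) attainable sum for a named group."""
        items = self.group_items(group)
        return (sum(it.min_level for it in items),
                sum(it.max_level for it in items))

    @property
    def total_range(self) -> tuple[int, int]:
        """(min, max) attainable sum over all items of the scale."""
        return (sum(it.min_level for it in self.items),
                sum(it.max_level for it in self.items))


def _parse_scale_mapping(cfg: Mapping) -> OrdinalScale:
    for key in ("name", "items"):
        if key not in cfg:
            raise ValidationError(f"scale config is missing required key '{key}'")
    items = []
    for raw in cfg["items"]:
        try:
            items.append(ItemDefinition(
                item_id=str(raw["id"]),
                label=str(raw.get("label", "")),
                section=str(raw.get("section", "")),
                min_level=int(raw.get("min", 0)),
                max_level=int(raw.get("max", 2)),
            ))
        except KeyError as exc:
            raise ValidationError(f"item entry {raw!r} is missing key {exc}") from exc
    groups = {str(g): tuple(str(m) for m in members)
              for g, members in (cfg.get("sum_groups") or {}).items()}
    return OrdinalScale(name=str(cfg["name"]), items=tuple(items), sum_groups=groups)


def load_scale(source: Union[str, Path, Mapping, OrdinalScale]) -> OrdinalScale:
    """Load and validate an ordinal scale.

    ``source`` may be the built-in name ``"fma_le"``, a path to a YAML/JSON
    config (keys ``name``, ``items`` [{id,label,section,min,max}],
    ``sum_groups`` {name: [ids]}), an already-parsed mapping, or an
    :class:`OrdinalScale` (returned unchanged).
    """
    if isinstance(source, OrdinalScale):
        return source
    if isinstance(source, Mapping):
        return _parse_scale_mapping(source)
    if source == "fma_le":
        text = resources.files("rankagree").joinpath("data/fma_le.yaml").read_text()
        return _parse_scale_mapping(yaml.safe_load(text))
    path = Path(source)
    if not path.exists():
        raise ValidationError(
            f"scale '{source}' is neither a built-in name nor an existing file"
        )
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, Mapping):
        raise ValidationError(f"scale config {path} does not parse to a mapping")
    return _parse_scale_mapping(cfg)


@dataclass
class RatingsDataset:
    """Validated long-format ratings for a multi-rater, multi-occasion study.

    ``df`` holds one row per (subject_id, rater_id, occasion, item_id) with an
    integer ``score``; extra columns are carried along as uninterpreted
    subject metadata.
    """

    df: pd.DataFrame
    scale: OrdinalScale

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    @property
    def raters(self) -> list[str]:
        return sorted(self.df["rater_id"].unique())

    @property
    def occasions(self) -> list[int]:
        return sorted(int(o) for o in self.df["occasion"].unique())

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in REQUIRED_COLUMNS]

    def to_csv(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, index=False)


def load_ratings(source: Union[str, Path, pd.DataFrame, RatingsDataset],
                 scale: Union[str, Path, Mapping, OrdinalScale]) -> RatingsDataset:
    """Read and validate ratings from delimited text (CSV/TSV) or a DataFrame.

    Validation: required columns present, occasions positive integers, every
    item_id known to the scale, every score inside its item's level range,
    and no duplicate (subject, rater, occasion, item) key.  Errors name the
    offending record.
    """
    scale = load_scale(scale)
    if isinstance(source, RatingsDataset):
        df = source.df.copy()
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"ratings are missing required column(s) {missing}")

    df = df.reset_index(drop=True)
    df["subject_id"] = df["subject_id"].astype(str)
    df["rater_id"] = df["rater_id"].astype(str)
    df["item_id"] = df["item_id"].astype(str)
    for col in ("occasion", "score"):
        try:
            df[col] = df[col].astype(int)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column '{col}' is not integer-valued: {exc}") from exc

    if (df["occasion"] < 1).any():
        row = df[df["occasion"] < 1].iloc[0]
        raise ValidationError(
            f"occasion must be a positive integer; got {row['occasion']} "
            f"(subject '{row['subject_id']}', rater '{row['rater_id']}')"
        )

    known = set(scale.item_ids)
    bad_items = df.loc[~df["item_id"].isin(known), "item_id"]
    if not bad_items.empty:
        raise ValidationError(
            f"unknown item_id '{bad_items.iloc[0]}' (row {bad_items.index[0]}) "
            f"for scale '{scale.name}'"
        )

    lo = df["item_id"].map({it.item_id: it.min_level for it in scale.items})
    hi = df["item_id"].map({it.item_id: it.max_level for it in scale.items})
    out = (df["score"] < lo) | (df["score"] > hi)
    if out.any():
        row = df[out].iloc[0]
        raise ValidationError(
            f"row {df[out].index[0]}: score {row['score']} outside "
            f"[{lo[out].iloc[0]}, {hi[out].iloc[0]}] for item '{row['item_id']}' "
            f"(subject '{row['subject_id']}', rater '{row['rater_id']}', "
            f"occasion {row['occasion']})"
        )

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            "duplicate rating for (subject '{s}', rater '{r}', occasion {o}, "
            "item '{i}')".format(s=row["subject_id"], r=row["rater_id"],
                                 o=row["occasion"], i=row["item_id"])
        )
    return RatingsDataset(df=df, scale=scale)


def sum_scores(data: RatingsDataset, scale: OrdinalScale, group: str) -> pd.DataFrame:
    """Sum a group's item scores per (subject, rater, occasion) assessment.

    Assessments missing one or more of the group's items are excluded and
    logged; the returned frame has columns subject_id, rater_id, occasion,
    score (the integer sum, within the group's attainable range).
    """
    members = scale.sum_groups.get(group)
    if members is None:
        raise ValidationError(
            f"unknown sum group '{group}' (available: {sorted(scale.sum_groups)})"
        )
    sub = data.df[data.df["item_id"].isin(members)]
    grouped = sub.groupby(["subject_id", "rater_id", "occasion"], sort=True)
    agg = grouped["score"].agg(["sum", "count"]).reset_index()
    incomplete = agg[agg["count"] < len(members)]
    if not incomplete.empty:
        for _, row in incomplete.iterrows():
            logger.warning(
                "sum_scores[%s]: excluding assessment (subject '%s', rater '%s', "
                "occasion %d) with %d of %d items present",
                group, row["subject_id"], row["rater_id"], row["occasion"],
                row["count"], len(members),
            )
    complete = agg[agg["count"] == len(members)]
    out = complete[["subject_id", "rater_id", "occasion"]].copy()
    out["score"] = complete["sum"].astype(int)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class FloorCeilingReport:
    """Floor/ceiling screening of a score distribution.

    An effect is flagged when *strictly more* than ``threshold`` of subjects
    sit at the scale minimum (floor) or maximum (ceiling); with the
    conventional 15% threshold, 9 of 60 subjects at the maximum (exactly 15%)
    is *not* a ceiling effect.
    """

    n_subjects: int
    n_at_min: int
    n_at_max: int
    threshold: float = 0.15
    floor_effect: bool = False
    ceiling_effect: bool = False


def floor_ceiling(totals: Sequence[int], scale_min: int, scale_max: int,
                  threshold: float = 0.15) -> FloorCeilingReport:
    """Screen total scores for floor/ceiling effects (strict > threshold rule)."""
    totals = np.asarray(totals)
    if totals.size == 0:
        raise ValidationError("floor_ceiling requires at least one total score")
    if totals.min() < scale_min or totals.max() > scale_max:
        raise ValidationError(
            f"totals outside the scale range [{scale_min}, {scale_max}]"
        )
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly between 0 and 1")
    n = int(totals.size)
    n_min = int((totals == scale_min).sum())
    n_max = int((totals == scale_max).sum())
    return FloorCeilingReport(
        n_subjects=n,
        n_at_min=n_min,
        n_at_max=n_max,
        threshold=threshold,
        floor_effect=n_min / n > threshold,
        ceiling_effect=n_max / n > threshold,
    )
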