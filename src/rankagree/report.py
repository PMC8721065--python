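"""End-to-end reliability analysis: ratings in, agreement tables out.

``run_analysis`` reads a ratings file (or dataset), a scale, and a study
design, enumerates every intra- and inter-rater comparison, and computes per
item and per sum group: PA (with tolerance-PA and the minimum tolerance
reaching the satisfactory-agreement threshold for sum groups), RP, RC and RV
with percentile-bootstrap confidence intervals and disagreement flags, plus
a floor/ceiling screen of the total score at the first occasion.

``write_report`` emits a PA table (units x comparisons, mirroring the layout
reliability papers print), one measure table per comparison with display
rounding, ROC coordinate files on request, and a JSON file carrying the
full-precision values; with the same inputs, options and seed the JSON is
byte-identical across runs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __about__
from .errors import ValidationError
from .inference import DisagreementFlag, IntervalEstimate, bootstrap_ci, classify, display_value
from .pairing import (ComparisonSpec, build_contingency, enumerate_comparisons,
                      extract_pairs, infer_pairing, load_design)
from .scale import (FloorCeilingReport, OrdinalScale, RatingsDataset,
                    floor_ceiling, load_ratings, load_scale, sum_scores)
from .svensson import agreement_estimates, roc_points

logger = logging.getLogger(__name__)

MEASURES = ("RP", "RC", "RV")


@dataclass
class ReliabilityReport:
    """Full analysis output: PA table, per-comparison measure tables,
    floor/ceiling screen and run metadata."""

    pa_table: pd.DataFrame
    measure_tables: dict[str, pd.DataFrame]
    floor_ceiling: Optional[FloorCeilingReport]
    metadata: dict


def _total_group(scale: OrdinalScale) -> Optional[str]:
    """The sum group spanning every item of the scale, if one is defined."""
    all_items = set(scale.item_ids)
    for name, members in scale.sum_groups.items():
        if set(members) == all_items:
            return name
    return None


def _floor_ceiling_screen(data: RatingsDataset, scale: OrdinalScale,
                          threshold: float) -> Optional[FloorCeilingReport]:
    group = _total_group(scale)
    if group is None:
        logger.info("no sum group spans the whole scale; skipping floor/ceiling")
        return None
    totals = sum_scores(data, scale, group)
    first_occ = min(data.occasions)
    totals = totals[totals["occasion"] == first_occ]
    # one total per subject: the first-listed rater of each subject's pair
    pairing = infer_pairing(data)
    keep = [
        row["rater_id"] == pairing.get(row["subject_id"], (row["rater_id"],))[0]
        for _, row in totals.iterrows()
    ]
    totals = totals[keep]
    if totals.empty:
        return None
    gmin, gmax = scale.group_range(group)
    return floor_ceiling(totals["score"].tolist(), gmin, gmax, threshold=threshold)


def run_analysis(ratings: Union[str, Path, pd.DataFrame, RatingsDataset],
                 scale: Union[str, Path, Mapping, OrdinalScale] = "fma_le",
                 design: Union[str, Path, Mapping, None] = None,
                 *,
                 tolerances: Sequence[int] = (1, 2),
                 threshold: float = 70.0,
                 fc_threshold: float = 0.15,
                 B: int = 2000,
                 level: float = 0.95,
                 seed: Optional[int] = None,
                 units: Optional[Sequence[str]] = None) -> ReliabilityReport:
    """Run the complete agreement analysis.

    ``tolerances`` are the accepted point differences reported for sum
    groups; ``threshold`` is the satisfactory-PA percentage used for the
    minimum-tolerance search; ``B``/``level``/``seed`` control the bootstrap.
    Deterministic given the seed.
    """
    scale = load_scale(scale)
    data = load_ratings(ratings, scale)
    specs = enumerate_comparisons(data, design)
    if not specs:
        raise ValidationError("the data support no intra- or inter-rater comparison")
    if units is None:
        units = list(scale.item_ids) + list(scale.sum_groups)
    group_names = set(scale.sum_groups)

    root_ss = np.random.SeedSequence(seed)
    logger.info("run_analysis: %d comparisons x %d units, B=%d, seed=%s",
                len(specs), len(units), B, seed)

    pa_columns: dict[str, dict[str, float]] = {}
    measure_tables: dict[str, pd.DataFrame] = {}

    for spec in specs:
        rows = []
        pa_col: dict[str, float] = {}
        for unit in units:
            uspec = dataclasses.replace(spec, unit=unit)
            try:
                sample = extract_pairs(data, scale, uspec)
            except ValidationError as exc:
                logger.warning("skipping %s/%s: %s", spec.label, unit, exc)
                rows.append({"unit": unit, "n": 0})
                continue
            table = build_contingency(sample)
            is_group = unit in group_names
            ests = agreement_estimates(
                table, tolerances=tolerances if is_group else (),
                threshold_percent=threshold,
            )
            pa_col[unit] = ests.PA
            if is_group:
                for k, pa in ests.pa_k.items():
                    pa_col[f"{unit} (±{k})"] = pa
            row = {"unit": unit, "n": sample.n, "PA": ests.PA}
            if is_group:
                row["min_tolerance"] = ests.min_k
                for k, pa in ests.pa_k.items():
                    row[f"PA_{k}"] = pa
            for meas in MEASURES:
                child = root_ss.spawn(1)[0]
                ci = bootstrap_ci(table, meas, B=B, level=level, seed=child)
                flag = classify(ci)
                row[meas] = ci.estimate
                row[f"{meas}_lower"] = ci.lower
                row[f"{meas}_upper"] = ci.upper
                row[f"{meas}_flag"] = flag.value
                row[f"{meas}_display"] = display_value(ci.estimate)
            rows.append(row)
        measure_tables[spec.label] = pd.DataFrame(rows).set_index("unit")
        pa_columns[spec.label] = pa_col

    # PA table: rows = units (+ tolerance rows for groups), columns = comparisons
    row_order: list[str] = []
    for unit in units:
        row_order.append(unit)
        if unit in group_names:
            row_order.extend(f"{unit} (±{int(k)})" for k in tolerances)
    pa_table = pd.DataFrame(pa_columns).reindex(row_order)
    pa_table.index.name = "unit"

    fc = _floor_ceiling_screen(data, scale, fc_threshold)

    metadata = {
        "package": "rankagree",
        "version": __about__.__version__,
        "scale": scale.name,
        "comparisons": [s.label for s in specs],
        "units": list(units),
        "tolerances": [int(k) for k in tolerances],
        "pa_threshold": threshold,
        "floor_ceiling_threshold": fc_threshold,
        "bootstrap_B": B,
        "confidence_level": level,
        "seed": seed,
        "n_subjects": len(data.subjects),
    }
    return ReliabilityReport(pa_table=pa_table, measure_tables=measure_tables,
                             floor_ceiling=fc, metadata=metadata)


def _safe_name(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label)


def report_to_dict(report: ReliabilityReport) -> dict:
    """Full-precision, JSON-serialisable view of a report."""
    def frame(df: pd.DataFrame) -> dict:
        out = {}
        for unit, row in df.iterrows():
            cells = {}
            for key, val in row.items():
                if isinstance(val, (np.floating, float)):
                    if pd.isna(val):
                        continue
                    cells[key] = float(val)
                elif isinstance(val, (np.integer, int)):
                    cells[key] = int(val)
                else:
                    cells[key] = val
            out[str(unit)] = cells
        return out

    fc = report.floor_ceiling
    return {
        "metadata": report.metadata,
        "pa_table": frame(report.pa_table),
        "measures": {label: frame(df) for label, df in report.measure_tables.items()},
        "floor_ceiling": None if fc is None else {
            "n_subjects": fc.n_subjects,
            "n_at_min": fc.n_at_min,
            "n_at_max": fc.n_at_max,
            "threshold": fc.threshold,
            "floor_effect": fc.floor_effect,
            "ceiling_effect": fc.ceiling_effect,
        },
    }


def write_report(report: ReliabilityReport, out_dir: Union[str, Path],
                 formats: Sequence[str] = ("csv", "json")) -> list[Path]:
    """Write the report to ``out_dir``; returns the paths written.

    CSV tables use display rounding (PA to one decimal, RP/RC/RV through
    :func:`rankagree.inference.display_value`); the JSON carries unrounded
    values and is byte-stable for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "csv" in formats:
        path = out_dir / "pa_table.csv"
        report.pa_table.round(1).to_csv(path)
        written.append(path)
        for label, df in report.measure_tables.items():
            disp = df.copy()
            if "PA" in disp.columns:
                disp["PA"] = disp["PA"].round(1)
            for meas in MEASURES:
                if meas not in disp.columns:
                    continue
                disp[meas] = df[meas].map(
                    lambda v: display_value(v) if pd.notna(v) else "")
                disp[f"{meas}_CI"] = [
                    "" if pd.isna(lo) else f"({lo:.2f}, {hi:.2f})"
                    for lo, hi in zip(df[f"{meas}_lower"], df[f"{meas}_upper"])
                ]
                disp = disp.drop(columns=[f"{meas}_lower", f"{meas}_upper",
                                          f"{meas}_display"])
            path = out_dir / f"measures_{_safe_name(label)}.csv"
            disp.to_csv(path)
            written.append(path)

    if "json" in formats:
        path = out_dir / "report.json"
        with open(path, "w") as fh:
            json.dump(report_to_dict(report), fh, indent=1, sort_keys=True)
        written.append(path)
    return written


def export_roc(ratings: Union[str, Path, pd.DataFrame, RatingsDataset],
               scale: Union[str, Path, Mapping, OrdinalScale],
               spec: ComparisonSpec, out_path: Union[str, Path]) -> Path:
    """Write one comparison/unit ROC curve as two-column delimited text."""
    scale = load_scale(scale)
    data = load_ratings(ratings, scale)
    sample = extract_pairs(data, scale, spec)
    curve = roc_points(build_contingency(sample))
    out_path = Path(out_path)
    df = pd.DataFrame(curve.points, columns=["cum_first", "cum_second"])
    df.to_csv(out_path, index=False)
    return out_path


def find_comparison(data: RatingsDataset, design, token: str) -> ComparisonSpec:
    """Resolve a comparison token like ``intra:A`` or ``inter:1``."""
    specs = enumerate_comparisons(data, design)
    mode, _, key = token.partition(":")
    for spec in specs:
        if spec.label == token:
            return spec
        if mode == "intra" and spec.mode == "intra" and spec.first[0] == key:
            return spec
        if mode == "inter" and spec.mode == "inter" and str(spec.first[1]) == key:
            return spec
    raise ValidationError(
        f"no comparison matches '{token}' (available: {[s.label for s in specs]})"
    )
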