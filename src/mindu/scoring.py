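"""Quartile thresholds, 5/3/1 metric scoring and the MINDU index.

Each retained metric is standardized against the least-impacted-station
(LIS) development data through its five-number summary (min, Q1, median,
Q3, max; spreadsheet-inclusive quantiles).  A sample's metric value then
earns a discrete score:

* metrics predicted to *increase* with pollution:
  5 if value < Q3, 3 if Q3 <= value <= max, 1 if value > max;
* metrics predicted to *decrease* with pollution:
  5 if value >= Q1, 3 if min <= value < Q1, 1 if value < min.

The index is the sum of the five metric scores (range 5-25) and maps to
a water-quality class: 22-25 B (very good), 18-21 C (good), 14-17 D
(fair), 10-13 E (poor), 5-9 F (very poor).  The published Niger Delta
urban parameterization ships with the package (``load_packaged_mindu``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import ValidationError, quantile

__all__ = [
    "CLASS_BANDS",
    "IndexResult",
    "derive_thresholds",
    "validate_thresholds",
    "score_metric_value",
    "compute_index",
    "classify_score",
    "load_packaged_mindu",
    "score_samples",
]

#: (low, high, class letter, label), covering every attainable sum.
CLASS_BANDS = (
    (5, 9, "F", "very poor"),
    (10, 13, "E", "poor"),
    (14, 17, "D", "fair"),
    (18, 21, "C", "good"),
    (22, 25, "B", "very good"),
)

THRESHOLD_COLUMNS = ("direction", "min", "q25", "q50", "q75", "max")


@dataclass(frozen=True)
class IndexResult:
    """Scored sample: per-metric scores, summed index, class and label."""

    metric_scores: dict
    mindu: int
    wq_class: str
    label: str


def validate_thresholds(table: pd.DataFrame) -> None:
    missing = set(THRESHOLD_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"threshold table missing columns {sorted(missing)}")
    for metric, row in table.iterrows():
        if row["direction"] not in ("increase", "decrease"):
            raise ValidationError(
                f"metric {metric!r}: bad direction {row['direction']!r}"
            )
        stats = [row[c] for c in ("min", "q25", "q50", "q75", "max")]
        if any(not np.isfinite(float(s)) for s in stats):
            raise ValidationError(f"metric {metric!r}: non-finite threshold")
        if not all(a <= b for a, b in zip(stats, stats[1:])):
            raise ValidationError(
                f"metric {metric!r}: thresholds must be non-decreasing, got {stats}"
            )


def derive_thresholds(lis_values: dict, directions: dict) -> pd.DataFrame:
    """Five-number summaries of LIS development data, per metric.

    ``lis_values`` maps metric name -> values observed at the
    least-impacted stations; ``directions`` maps metric name ->
    increase/decrease.  Quartiles use the inclusive linear-interpolation
    rule throughout.
    """
    rows = {}
    for metric, values in lis_values.items():
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) < 4:
            raise ValidationError(
                f"metric {metric!r}: need >= 4 LIS values, got {len(v)}"
            )
        if metric not in directions:
            raise ValidationError(f"metric {metric!r}: no direction given")
        q25, q50, q75 = quantile(v, [25, 50, 75])
        rows[metric] = {
            "direction": directions[metric],
            "min": float(v.min()),
            "q25": float(q25),
            "q50": float(q50),
            "q75": float(q75),
            "max": float(v.max()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[
        list(lis_values), list(THRESHOLD_COLUMNS)
    ]
    table.index.name = "metric"
    validate_thresholds(table)
    return table


def score_metric_value(value: float, thresholds: pd.Series) -> int | None:
    """Score one metric value against its threshold row; None if missing.

    Band edges: for increase-direction metrics a value exactly at Q3
    takes the poorer score 3 (conservative for protection) and the max
    is inclusive in band 3; for decrease-direction metrics Q1 is
    inclusive in band 5 and the min in band 3.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    v = float(value)
    d = thresholds["direction"]
    if d == "increase":
        if v < thresholds["q75"]:
            return 5
        if v <= thresholds["max"]:
            return 3
        return 1
    if d == "decrease":
        if v >= thresholds["q25"]:
            return 5
        if v >= thresholds["min"]:
            return 3
        return 1
    raise ValidationError(f"bad direction {d!r}")


def classify_score(mindu: int) -> tuple[str, str]:
    for lo, hi, cls, label in CLASS_BANDS:
        if lo <= mindu <= hi:
            return cls, label
    raise ValidationError(f"index value {mindu} outside 5-25")


def compute_index(metric_scores: dict) -> IndexResult:
    """Sum the five metric scores and attach the water-quality class."""
    if not metric_scores:
        raise ValidationError("no metric scores")
    for m, s in metric_scores.items():
        if s not in (1, 3, 5):
            raise ValidationError(f"metric {m!r}: score must be 1/3/5, got {s!r}")
    total = int(sum(metric_scores.values()))
    cls, label = classify_score(total)
    return IndexResult(dict(metric_scores), total, cls, label)


def load_packaged_mindu() -> pd.DataFrame:
    """The published five-metric Niger Delta urban index thresholds.

    Indexed by registry metric name, with a ``code`` column carrying the
    conventional short codes (Hem Abun, %Col + Hem, %Chi + Oli, Even
    Ind, Log VeL); threshold values are exactly the published ones.
    """
    with resources.files("mindu.data").joinpath("mindu_thresholds.csv").open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index("metric")
    validate_thresholds(df)
    return df


def score_samples(matrix: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Score every sampling occasion of a metric matrix.

    ``matrix`` must contain a column for every threshold metric (matched
    by name, falling back to the ``code`` column of packaged tables).
    Returns one row per occasion with the per-metric scores, the summed
    index, class and label; occasions with any missing metric value are
    flagged unscorable (NaN index, empty class).
    """
    colmap = {}
    for metric in thresholds.index:
        if metric in matrix.columns:
            colmap[metric] = metric
        elif "code" in thresholds.columns and thresholds.loc[metric, "code"] in matrix.columns:
            colmap[metric] = thresholds.loc[metric, "code"]
        else:
            raise ValidationError(f"metric {metric!r} absent from the matrix")
    out = []
    for idx, row in matrix.iterrows():
        scores = {
            m: score_metric_value(row[colmap[m]], thresholds.loc[m])
            for m in thresholds.index
        }
        rec = {f"score:{m}": s for m, s in scores.items()}
        if any(s is None for s in scores.values()):
            rec.update({"mindu": math.nan, "wq_class": "", "label": "",
                        "scorable": False})
        else:
            res = compute_index(scores)
            rec.update({"mindu": res.mindu, "wq_class": res.wq_class,
                        "label": res.label, "scorable": True})
        out.append(rec)
    return pd.DataFrame(out, index=matrix.index)
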