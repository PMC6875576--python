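"""Index validation: correspondence with the physicochemical categories.

Performance of a multimetric index is summarized as the percent of
sampling occasions in each impact category whose water-quality label is
deemed acceptable for that category:

* LIS — very good or good,
* MIS — good or fair,
* HIS — fair, poor or very poor.

Percentages are always taken over all of a category's occasions (both
seasons pooled), so the per-season cells of the seasonal breakdown sum
to the overall cells.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import ValidationError
from .scoring import CLASS_BANDS

__all__ = ["DEFAULT_RULE", "LABELS", "correspondence", "seasonal_correspondence"]

LABELS = tuple(band[3] for band in CLASS_BANDS)  # very poor .. very good

#: Acceptable water-quality labels per impact category.
DEFAULT_RULE = {
    "LIS": ("very good", "good"),
    "MIS": ("good", "fair"),
    "HIS": ("fair", "poor", "very poor"),
}

_CAT_NAMES = {1: "LIS", 2: "MIS", 3: "HIS"}


def _normalize(results: pd.DataFrame) -> pd.DataFrame:
    df = results.copy()
    if "category" not in df.columns or "label" not in df.columns:
        raise ValidationError("results need 'category' and 'label' columns")
    df["category"] = df["category"].map(lambda v: _CAT_NAMES.get(v, v))
    bad = set(df["category"]) - set(DEFAULT_RULE)
    if bad:
        raise ValidationError(f"unknown categories {sorted(bad)}")
    return df


def correspondence(results: pd.DataFrame, rule=None) -> pd.DataFrame:
    """Per-category label histogram and correspondence percentage.

    ``results`` carries one row per scored occasion with columns
    ``category`` (LIS/MIS/HIS or 1/2/3) and ``label`` (water-quality
    label).  Returns a frame indexed by category with ``n``, one percent
    column per label, and ``correspondence``; categories with no
    occasions are reported with NaN percentages.
    """
    rule = rule or DEFAULT_RULE
    df = _normalize(results)
    rows = {}
    for cat in ("LIS", "MIS", "HIS"):
        sub = df[df["category"] == cat]
        n = len(sub)
        if n == 0:
            rows[cat] = {"n": 0, **{lab: math.nan for lab in LABELS},
                         "correspondence": math.nan}
            continue
        pct = {lab: 100.0 * (sub["label"] == lab).sum() / n for lab in LABELS}
        rows[cat] = {
            "n": n,
            **pct,
            "correspondence": sum(pct[lab] for lab in rule[cat]),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "category"
    return out


def seasonal_correspondence(results: pd.DataFrame, rule=None) -> pd.DataFrame:
    """Correspondence stratified by season.

    Cell percentages use the category's total occasions (both seasons)
    as denominator, so each category's wet and dry cells sum to its
    overall histogram.  Returns a frame indexed by (category, season);
    a season absent from a category appears with NaN percentages.
    """
    rule = rule or DEFAULT_RULE
    df = _normalize(results)
    if "season" not in df.columns:
        raise ValidationError("seasonal correspondence needs a 'season' column")
    rows = {}
    for cat in ("LIS", "MIS", "HIS"):
        sub = df[df["category"] == cat]
        n_total = len(sub)
        for season in ("wet", "dry"):
            ss = sub[sub["season"] == season]
            if n_total == 0 or len(ss) == 0:
                rows[(cat, season)] = {
                    "n": len(ss), **{lab: math.nan for lab in LABELS},
                    "correspondence": math.nan,
                }
                continue
            pct = {
                lab: 100.0 * (ss["label"] == lab).sum() / n_total
                for lab in LABELS
            }
            rows[(cat, season)] = {
                "n": len(ss),
                **pct,
                "correspondence": sum(pct[lab] for lab in rule[cat]),
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["category", "season"])
    return out
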