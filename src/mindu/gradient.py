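"""Pollution-gradient site delineation from physicochemistry.

Stations are placed along an urban-impact gradient by principal component
analysis of their physicochemical profiles.  Each station's score on the
first axis is converted to an interstation distance (distance from the
most-impacted, i.e. highest-scoring, station), rescaled to a 0-100
percent distance, and the percentile distribution of those percent
distances is cut to assign impact categories:

* LIS (least impacted)      percent distance >= 90th percentile
* MIS (moderately impacted) 50th percentile <= percent distance < 90th
* HIS (heavily impacted)    percent distance < 50th percentile

The axis is oriented so that the BOD5 loading is positive, making higher
coordinates more impacted; the station farthest from the impacted end
therefore carries percent distance 100.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import PhysChemTable, RunConfig, ValidationError, quantile

__all__ = [
    "CATEGORY_LABELS",
    "DegenerateAxisError",
    "compute_gradient_axis",
    "interstation_percent_distances",
    "categorize_stations",
    "delineate",
]

#: Category codes and labels; 1 is cleanest, 3 most impacted.
CATEGORY_LABELS = {1: "LIS", 2: "MIS", 3: "HIS"}

#: Variables whose first-axis loading fixes the orientation (first present
#: wins); all increase with urban pollution.
_ORIENT_POSITIVE = ("bod5", "ec", "nitrate", "phosphate")


class DegenerateAxisError(ValidationError):
    """The variable matrix carries no variance to build an axis from."""


def compute_gradient_axis(physchem: PhysChemTable, scale: bool = True) -> pd.Series:
    """Score every station on the first principal component.

    Parameters
    ----------
    physchem
        Station x variable table of per-station means.
    scale
        Standardize variables to unit variance (correlation-matrix PCA).
        The variables have heterogeneous units, so this is the default;
        ``scale=False`` runs the covariance-matrix variant.

    Returns
    -------
    pandas.Series mapping station -> axis-1 coordinate, sign-fixed so
    that the BOD5 (else EC/nitrate/phosphate, else -DO) loading is
    positive: larger coordinate = more impacted.
    """
    df = physchem.data
    if len(df) < 3:
        raise ValidationError(f"need >= 3 stations for delineation, got {len(df)}")
    sd = df.std(ddof=1)
    keep = sd[sd > 0].index
    if len(keep) < 2:
        raise DegenerateAxisError(
            "need >= 2 variables with nonzero variance across stations"
        )
    X = df[keep].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = pd.Series(vt[0], index=keep)

    sign = 0.0
    for var in _ORIENT_POSITIVE:
        if var in loadings.index and loadings[var] != 0:
            sign = np.sign(loadings[var])
            break
    if sign == 0.0 and "do" in loadings.index and loadings["do"] != 0:
        sign = -np.sign(loadings["do"])
    if sign == 0.0:
        warnings.warn(
            "no pollution-indicator variable available to orient the axis; "
            "keeping the arbitrary SVD sign",
            stacklevel=2,
        )
        sign = 1.0
    return pd.Series(scores * sign, index=df.index, name="axis1")


def interstation_percent_distances(coords: pd.Series) -> pd.DataFrame:
    """Distance of each station from the most-impacted end of the axis.

    distance_i = max(coords) - coords_i, and percent_i rescales distance
    to [0, 100]; the highest-scoring (most impacted) station gets 0 and
    the lowest-scoring (cleanest) gets 100.
    """
    coords = pd.Series(coords, dtype=float)
    if len(coords) < 2:
        raise ValidationError("need >= 2 stations for interstation distances")
    span = float(coords.max() - coords.min())
    if span == 0.0:
        raise ValidationError(
            "all axis coordinates are equal; percent distances undefined"
        )
    distance = coords.max() - coords
    percent = 100.0 * distance / span
    return pd.DataFrame({"distance": distance, "percent": percent})


def categorize_stations(
    percents: pd.Series,
    cutpoints: tuple[float, float] = (90.0, 50.0),
) -> pd.Series:
    """Cut the percent-distance distribution into impact categories.

    The hi/lo cutpoints (default 90th and 50th) are percentiles of the
    *empirical distribution of percent distances* (inclusive linear
    interpolation), not raw positions on the 0-100 scale; category
    boundaries are inclusive at the top (a station sitting exactly on a
    percentile joins the cleaner category).
    """
    percents = pd.Series(percents, dtype=float)
    if not np.isfinite(percents.to_numpy()).all():
        raise ValidationError("percent distances must be finite")
    hi, lo = cutpoints
    if len(percents) < 3:
        warnings.warn(
            "fewer than 3 stations: comparing percent distances directly "
            "to the cutpoint values",
            stacklevel=2,
        )
        p_hi, p_lo = float(hi), float(lo)
    else:
        p_hi = float(quantile(percents, hi))
        p_lo = float(quantile(percents, lo))
    cat = np.where(
        percents >= p_hi, 1, np.where(percents >= p_lo, 2, 3)
    )
    return pd.Series(cat, index=percents.index, name="category", dtype=int)


def delineate(
    physchem: PhysChemTable,
    config: RunConfig | None = None,
    scale: bool = True,
) -> pd.DataFrame:
    """Full delineation: axis scores, distances, percents and categories.

    Returns a station-indexed frame with columns ``axis1``, ``distance``,
    ``percent``, ``category`` (1/2/3) and ``label`` (LIS/MIS/HIS).
    """
    config = config or RunConfig()
    coords = compute_gradient_axis(physchem, scale=scale)
    dist = interstation_percent_distances(coords)
    cat = categorize_stations(dist["percent"], config.percentile_cutpoints)
    out = pd.DataFrame(
        {
            "axis1": coords,
            "distance": dist["distance"],
            "percent": dist["percent"],
            "category": cat,
            "label": cat.map(CATEGORY_LABELS),
        }
    )
    out.index.name = "station"
    return out
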