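"""Tabular input/output and run configuration.

Three tables drive an index-building run: a long-format macroinvertebrate
abundance table (one composite sample per station per sampling date), a
wide-format physicochemical table (per-station means of the measured
variables), and an optional taxon x trait-modality fuzzy-affinity table
with 0-3 integer scores.  All are plain CSV (TSV accepted via a flag),
UTF-8, with a header row.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "RunConfig",
    "AbundanceTable",
    "PhysChemTable",
    "TraitAffinityTable",
    "infer_season",
    "read_abundance_table",
    "read_physchem_table",
    "read_trait_table",
    "read_threshold_table",
    "write_results",
]


class SchemaError(ValueError):
    """A required column is absent or a table has the wrong shape."""


class ValidationError(ValueError):
    """A cell violates a declared invariant (reported with its row)."""


#: Months of the wet season (April-September); the rest are dry.
WET_MONTHS = frozenset(range(4, 10))

SEASONS = ("wet", "dry")


def infer_season(date: _dt.date) -> str:
    """Season of a calendar date: wet for April-September, dry otherwise."""
    return "wet" if date.month in WET_MONTHS else "dry"


@dataclass(frozen=True)
class RunConfig:
    """Knobs shared across the screening/scoring pipeline.

    alpha
        Significance level of every hypothesis test (Mann-Whitney,
        Kruskal-Wallis, Spearman).
    spearman_cutoff
        Absolute rank-correlation at or above which two metrics are
        declared redundant (inclusive).
    percentile_cutpoints
        (hi, lo) percentiles of the percent-distance distribution used to
        split stations into least/moderately/heavily impacted.
    quantile_rule
        Identifier of the quantile convention; only the spreadsheet
        inclusive linear-interpolation rule is implemented.
    """

    alpha: float = 0.05
    spearman_cutoff: float = 0.78
    percentile_cutpoints: tuple[float, float] = (90.0, 50.0)
    quantile_rule: str = "excel-inclusive"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.spearman_cutoff <= 1.0:
            raise ValidationError(
                f"spearman_cutoff must be in (0, 1], got {self.spearman_cutoff}"
            )
        hi, lo = self.percentile_cutpoints
        if not (0.0 < lo < hi < 100.0):
            raise ValidationError(
                f"percentile cutpoints must be strictly decreasing within "
                f"(0, 100), got {self.percentile_cutpoints}"
            )
        if self.quantile_rule != "excel-inclusive":
            raise ValidationError(f"unknown quantile rule {self.quantile_rule!r}")


def quantile(values, q) -> float | np.ndarray:
    """Spreadsheet-inclusive quantile (linear interpolation between order
    statistics) at percentile ``q`` in [0, 100].

    This single convention is used everywhere quartiles or percentiles
    appear: gradient cutpoints, box-plot discrimination and scoring
    thresholds.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot take a quantile of an empty sequence")
    return np.percentile(arr, q, method="linear")


# ---------------------------------------------------------------------------
# Abundance table


@dataclass(frozen=True)
class AbundanceTable:
    """Sample-level taxon counts keyed by (station, date, season).

    One row per (station, date, taxon); counts are non-negative integers
    of individuals in the composite sample for that occasion.
    """

    data: pd.DataFrame  # columns: station, date, season, taxon, count

    COLUMNS = ("station", "date", "season", "taxon", "count")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        df = df.loc[:, list(cls.COLUMNS)].reset_index(drop=True)
        _validate_abundance(df)
        return cls(df)

    def samples(self) -> Iterator[tuple[tuple[str, _dt.date, str], dict[str, int]]]:
        """Yield ((station, date, season), {taxon: count}) per occasion."""
        for key, grp in self.data.groupby(["station", "date", "season"], sort=True):
            yield key, dict(zip(grp["taxon"], grp["count"].astype(int)))

    @property
    def stations(self) -> list[str]:
        return sorted(self.data["station"].unique())

    def __len__(self) -> int:
        return len(self.data)


def _validate_abundance(df: pd.DataFrame) -> None:
    for i, c in df["count"].items():
        try:
            ok = not pd.isna(c) and float(c) == int(c) and int(c) >= 0
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise ValidationError(
                f"row {i}: count must be a non-negative integer, got {c!r}"
            )
    df["count"] = df["count"].astype(int)
    dup = df.duplicated(subset=["station", "date", "taxon"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate (station, date, taxon) record: "
            f"({r['station']}, {r['date']}, {r['taxon']})"
        )
    for i, (d, s) in enumerate(zip(df["date"], df["season"])):
        if s not in SEASONS:
            raise ValidationError(f"row {i}: season must be wet or dry, got {s!r}")
        if infer_season(d) != s:
            raise ValidationError(
                f"row {i}: season {s!r} inconsistent with date {d} "
                f"(month {d.month} is {infer_season(d)})"
            )


def read_abundance_table(path, dialect: str = "csv") -> AbundanceTable:
    """Read a long-format abundance CSV/TSV.

    Required columns: station, date, taxon, count.  A season column is
    optional; when absent the season is inferred from the month
    (April-September wet, October-March dry), and when present it must
    agree with the inference on every row.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"station", "date", "taxon", "count"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    try:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable date: {exc}") from exc
    df["station"] = df["station"].astype(str)
    df["taxon"] = df["taxon"].astype(str)
    if "season" in df.columns:
        df["season"] = df["season"].astype(str).str.strip().str.lower()
    else:
        df["season"] = [infer_season(d) for d in df["date"]]
    return AbundanceTable.from_frame(df)


# ---------------------------------------------------------------------------
# Physicochemical table

#: Canonical variable names and accepted aliases.
PHYSCHEM_ALIASES = {
    "temperature": "temperature",
    "water_temperature": "temperature",
    "temp": "temperature",
    "depth": "depth",
    "flow": "flow",
    "flow_velocity": "flow",
    "velocity": "flow",
    "ec": "ec",
    "conductivity": "ec",
    "electrical_conductivity": "ec",
    "ph": "ph",
    "do": "do",
    "dissolved_oxygen": "do",
    "bod5": "bod5",
    "bod": "bod5",
    "nitrate": "nitrate",
    "phosphate": "phosphate",
}

CANONICAL_VARIABLES = (
    "temperature", "depth", "flow", "ec", "ph", "do", "bod5",
    "nitrate", "phosphate",
)


@dataclass(frozen=True)
class PhysChemTable:
    """Per-station means of the physicochemical variables.

    ``data`` is indexed by station id; columns are variables in the
    units of the field campaign (temperature degC, depth m, flow m/s,
    EC uS/cm, DO and BOD5 mg/L, nutrients mg/L).
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhysChemTable":
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicated station id: {dup!r}")
        if df.index.isna().any():
            raise ValidationError("missing station id")
        vals = df.to_numpy(dtype=float)  # raises on non-numeric
        if not np.isfinite(vals).all():
            bad = df.index[~np.isfinite(vals).all(axis=1)][0]
            raise ValidationError(f"non-finite value at station {bad!r}")
        if "ph" in df.columns:
            ph = df["ph"]
            if ((ph < 0) | (ph > 14)).any():
                bad = df.index[(ph < 0) | (ph > 14)][0]
                raise ValidationError(
                    f"pH out of [0, 14] at station {bad!r}: {float(df.loc[bad, 'ph'])}"
                )
        return cls(df.astype(float))

    @property
    def stations(self) -> list[str]:
        return list(self.data.index)


def read_physchem_table(path, dialect: str = "csv") -> PhysChemTable:
    """Read a wide station x variable table; first column is the station id."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need a station column plus >=1 variable")
    station_col = df.columns[0]
    if "station" in [c.strip().lower() for c in df.columns]:
        station_col = next(c for c in df.columns if c.strip().lower() == "station")
    df = df.set_index(df[station_col].astype(str)).drop(columns=[station_col])
    df.index.name = "station"
    renamed, extras = {}, []
    for c in df.columns:
        key = str(c).strip().lower().replace(" ", "_")
        if key in PHYSCHEM_ALIASES:
            renamed[c] = PHYSCHEM_ALIASES[key]
        else:
            renamed[c] = key
            extras.append(key)
    df = df.rename(columns=renamed)
    if extras:
        warnings.warn(
            f"{path}: unknown variable(s) carried through: {extras}", stacklevel=2
        )
    try:
        return PhysChemTable.from_frame(df)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc


# ---------------------------------------------------------------------------
# Trait affinity table


@dataclass(frozen=True)
class TraitAffinityTable:
    """Fuzzy-coded taxon x trait-modality affinities.

    Each taxon holds an integer affinity in {0, 1, 2, 3} for every
    modality of a trait (0 = no affinity, 3 = high).  Within a trait the
    profile of a taxon is normalized to weights summing to one before
    trait metrics are computed; an all-zero profile contributes nothing.
    """

    data: pd.DataFrame  # columns: taxon, trait, trait_modality, affinity

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitAffinityTable":
        df = df.copy()
        if "trait" not in df.columns:
            df["trait"] = "body_size"
        aff = df["affinity"]
        for i, a in aff.items():
            if pd.isna(a) or float(a) != int(a) or int(a) not in (0, 1, 2, 3):
                raise ValidationError(
                    f"row {i}: affinity must be an integer in 0..3, got {a!r}"
                )
        df["affinity"] = df["affinity"].astype(int)
        dup = df.duplicated(subset=["taxon", "trait_modality"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate (taxon, modality): ({r['taxon']}, {r['trait_modality']})"
            )
        return cls(df.loc[:, ["taxon", "trait", "trait_modality", "affinity"]])

    @property
    def modalities(self) -> list[str]:
        return sorted(self.data["trait_modality"].unique())

    def modality_weights(self, modality: str) -> dict[str, float]:
        """Per-taxon weight of ``modality`` after normalizing each taxon's
        affinity profile within the trait that owns the modality."""
        rows = self.data[self.data["trait_modality"] == modality]
        if rows.empty:
            raise ValidationError(f"trait modality {modality!r} not in table")
        trait = rows["trait"].iloc[0]
        block = self.data[self.data["trait"] == trait]
        weights: dict[str, float] = {}
        for taxon, grp in block.groupby("taxon"):
            total = grp["affinity"].sum()
            if total == 0:
                weights[taxon] = 0.0
                continue
            sel = grp.loc[grp["trait_modality"] == modality, "affinity"]
            weights[taxon] = float(sel.iloc[0]) / total if len(sel) else 0.0
        return weights


def read_trait_table(path, dialect: str = "csv") -> TraitAffinityTable:
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"taxon", "trait_modality", "affinity"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    return TraitAffinityTable.from_frame(df)


def read_threshold_table(path) -> pd.DataFrame:
    """Read a per-metric threshold table (metric, direction, min..max)."""
    from . import scoring  # local import to avoid a cycle

    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"metric", "direction", "min", "q25", "q50", "q75", "max"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    df = df.set_index("metric")
    scoring.validate_thresholds(df)
    return df


# ---------------------------------------------------------------------------
# Generic writer


def write_results(obj, path) -> None:
    """Serialize a pipeline product to CSV (tabular) or JSON (records).

    DataFrames and the table wrappers go to CSV; mappings, dataclasses
    and sequences of dataclasses go to JSON.  Floats are written at full
    repr precision so a read-back reproduces them to >=12 significant
    digits.
    """
    path = Path(path)
    if isinstance(obj, (AbundanceTable, PhysChemTable, TraitAffinityTable)):
        index = isinstance(obj, PhysChemTable)
        obj.data.to_csv(path, index=index)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=not isinstance(obj.index, pd.RangeIndex))
    elif isinstance(obj, pd.Series):
        obj.to_frame().to_csv(path)
    elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        path.write_text(json.dumps(dataclasses.asdict(obj), default=str, indent=2))
    elif isinstance(obj, Mapping):
        path.write_text(json.dumps(dict(obj), default=str, indent=2))
    elif isinstance(obj, (list, tuple)):
        out = [
            dataclasses.asdict(o) if dataclasses.is_dataclass(o) else o for o in obj
        ]
        path.write_text(json.dumps(out, default=str, indent=2))
    else:
        raise ValidationError(f"do not know how to write {type(obj).__name__}")
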