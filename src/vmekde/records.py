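"""Trawl-survey point-biomass records: reading, validation, extents.

One row = one research-vessel trawl set: a projected planar start position
(meters), the catch weight (kg) of one taxon, and the survey/gear/duration
metadata needed to decide whether surveys can be pooled.  Coordinates must
arrive already projected (the numeric core is projection-agnostic); the
declared CRS is carried along as metadata only and never used to transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SurveyRecord",
    "Extent",
    "ConfigurationError",
    "RecordValidationError",
    "DegenerateExtentError",
    "CANONICAL_COLUMNS",
    "read_records",
    "write_records",
    "validate_records",
    "compute_tow_length",
    "data_extent",
    "positive_records",
]

#: Canonical column names of a record table, in export order.
CANONICAL_COLUMNS = [
    "x", "y", "biomass", "survey_id", "gear", "duration", "speed", "taxon",
]


class ConfigurationError(ValueError):
    """A problem with the run configuration (e.g. a required column missing)."""


class RecordValidationError(ValueError):
    """One or more rows violate the record invariants; carries row diagnostics."""

    def __init__(self, message: str, row_errors: list[tuple[int, str]]):
        super().__init__(message)
        self.row_errors = row_errors


class DegenerateExtentError(ValueError):
    """All points coincide (or fewer than two distinct locations exist)."""


@dataclass(frozen=True)
class SurveyRecord:
    """A single trawl set.

    Attributes
    ----------
    x, y : float
        Projected planar coordinates in meters (e.g. UTM easting/northing).
    biomass : float
        Catch weight in kg, >= 0.  Zero means a null set (nothing caught).
    survey_id, gear, taxon : str
        Categorical labels.  Gear examples: ``"Campelen"``, ``"Lofoten"``.
    duration : float
        Tow duration in minutes, > 0.
    speed : float or None
        Vessel speed in knots, > 0 when present; optional.
    """

    x: float
    y: float
    biomass: float
    survey_id: str = ""
    gear: str = ""
    duration: float = 30.0
    speed: float | None = None
    taxon: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite planar values")
        if self.biomass < 0:
            raise ValueError("biomass must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.speed is not None and self.speed <= 0:
            raise ValueError("speed must be > 0 when present")


@dataclass(frozen=True)
class Extent:
    """A planar bounding box in meters."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise DegenerateExtentError(
                f"degenerate extent: ({self.xmin}, {self.ymin}, "
                f"{self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def to_json(self) -> str:
        return json.dumps(
            {"xmin": self.xmin, "ymin": self.ymin,
             "xmax": self.xmax, "ymax": self.ymax}
        )

    @classmethod
    def from_json(cls, text: str) -> "Extent":
        d = json.loads(text)
        return cls(d["xmin"], d["ymin"], d["xmax"], d["ymax"])


def read_records(
    path,
    column_map: Mapping[str, str] | None = None,
    crs_note: str = "",
) -> pd.DataFrame:
    """Read trawl-set records from a delimited text file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row, decimal point ".", no thousands separators.
    column_map : mapping, optional
        Maps canonical names (``x``, ``y``, ``biomass``, ...) to the file's
        column names.  Unmapped canonical names are looked up verbatim.
    crs_note : str
        Free-text declaration of the projected CRS the coordinates are in
        (e.g. ``"UTM NAD83 Zone 23"``).  Stored in ``df.attrs["crs"]``.

    Returns
    -------
    pandas.DataFrame
        Canonical columns (missing optional ones filled with defaults), one
        row per trawl set, index preserved from file row order.  The number
        of zero-biomass (null) sets is recorded in
        ``df.attrs["n_zero_biomass"]``.

    Raises
    ------
    ConfigurationError
        If a required column (``x``, ``y``, ``biomass``) is absent.
    RecordValidationError
        If any row fails the record invariants; ``row_errors`` lists
        ``(row_index, reason)`` pairs.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path)

    def source(name: str) -> str:
        return column_map.get(name, name)

    for required in ("x", "y", "biomass"):
        if source(required) not in raw.columns:
            raise ConfigurationError(
                f"required column {source(required)!r} (for {required!r}) "
                f"not found in {path}"
            )

    df = pd.DataFrame(index=raw.index)
    for name in CANONICAL_COLUMNS:
        src = source(name)
        if src in raw.columns:
            df[name] = raw[src]
        elif name == "duration":
            df[name] = 30.0
        elif name == "speed":
            df[name] = np.nan
        else:
            df[name] = ""
    df = validate_records(df)
    df.attrs["crs"] = crs_note
    return df


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check record invariants row by row; raise with indexed diagnostics.

    Numeric columns are coerced; rows with non-numeric biomass, negative
    biomass, non-positive duration, non-positive declared speed or non-finite
    coordinates are collected into a single :class:`RecordValidationError`.
    """
    df = df.copy()
    row_errors: list[tuple[int, str]] = []
    for col in ("x", "y", "biomass", "duration", "speed"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if col != "speed":  # speed is genuinely optional, NaN allowed
            bad = coerced.isna() & df[col].notna() | df[col].isna()
            for idx in df.index[bad]:
                row_errors.append((int(idx), f"non-numeric {col}: {df.loc[idx, col]!r}"))
        df[col] = coerced

    ok = ~df.index.isin([i for i, _ in row_errors])
    for idx in df.index[ok & ~(np.isfinite(df["x"]) & np.isfinite(df["y"]))]:
        row_errors.append((int(idx), "non-finite coordinates"))
    for idx in df.index[ok & (df["biomass"] < 0)]:
        row_errors.append((int(idx), f"negative biomass: {df.loc[idx, 'biomass']}"))
    for idx in df.index[ok & ~(df["duration"] > 0)]:
        row_errors.append((int(idx), f"non-positive duration: {df.loc[idx, 'duration']}"))
    for idx in df.index[ok & (df["speed"] <= 0)]:
        row_errors.append((int(idx), f"non-positive speed: {df.loc[idx, 'speed']}"))

    if row_errors:
        row_errors.sort()
        raise RecordValidationError(
            f"{len(row_errors)} row(s) failed validation: "
            + "; ".join(f"row {i}: {msg}" for i, msg in row_errors[:5])
            + ("; ..." if len(row_errors) > 5 else ""),
            row_errors,
        )
    df.attrs["n_zero_biomass"] = int((df["biomass"] == 0).sum())
    return df


def write_records(df: pd.DataFrame, path) -> None:
    """Export validated records back to CSV (canonical columns, full precision)."""
    df.to_csv(path, index=False, columns=CANONICAL_COLUMNS)


def positive_records(df: pd.DataFrame) -> pd.DataFrame:
    """Records with strictly positive catch.

    Null (zero-biomass) sets are retained in the collection for diagnostics
    such as "isolated record surrounded by null sets", but are excluded from
    density estimation by default: the density surface is built from catches.
    """
    return df[df["biomass"] > 0]


def compute_tow_length(record) -> float:
    """Trawl length in nautical miles, ``speed [kn] * duration [h]``.

    Used for tow-length-vs-catch diagnostics.  Accepts a
    :class:`SurveyRecord`, a mapping, or a pandas row.  Returns ``nan`` when
    the speed is unavailable (missing speed is not an error).
    """
    if isinstance(record, SurveyRecord):
        speed, duration = record.speed, record.duration
    else:
        speed, duration = record["speed"], record["duration"]
    if speed is None or (isinstance(speed, float) and np.isnan(speed)):
        return float("nan")
    if speed <= 0:
        raise ValueError("speed must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return float(speed) * float(duration) / 60.0


def data_extent(records) -> Extent:
    """Tight bounding box of record locations.

    Parameters
    ----------
    records : DataFrame or iterable of SurveyRecord

    Raises
    ------
    DegenerateExtentError
        With fewer than two distinct locations, or all points on one
        horizontal/vertical line (zero width or height).
    """
    if isinstance(records, pd.DataFrame):
        xs = records["x"].to_numpy(dtype=float)
        ys = records["y"].to_numpy(dtype=float)
    else:
        pts = [(r.x, r.y) for r in records]
        xs = np.array([p[0] for p in pts], dtype=float)
        ys = np.array([p[1] for p in pts], dtype=float)
    if xs.size < 2:
        raise DegenerateExtentError("need at least 2 points for an extent")
    return Extent(float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max()))
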