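"""Long-format observation table for pixel time series.

The analysis operates on a "long table": one row per (pixel, date) with
columns ``longitude, latitude, date, gpp, year, month, day, war``.  The
``war`` column is a two-level factor splitting the record at an event
cutoff date (default 24 February 2022); the cutoff date itself is labelled
``post``.
"""

from __future__ import annotations

import warnings
from datetime import date as _date

import numpy as np
import pandas as pd

from .rasters import RasterStack

__all__ = [
    "DEFAULT_CUTOFF",
    "build_long_table",
    "add_calendar_columns",
    "label_event",
    "read_long_table",
    "write_long_table",
    "pixel_key",
]

DEFAULT_CUTOFF = pd.Timestamp(2022, 2, 24)

#: decimal degrees kept when forming the per-pixel grouping key
_KEY_DECIMALS = 6


def pixel_key(table: pd.DataFrame) -> pd.Series:
    """Stable per-pixel grouping key: lon/lat rounded to 1e-6 degrees."""
    lon = table["longitude"].round(_KEY_DECIMALS)
    lat = table["latitude"].round(_KEY_DECIMALS)
    return lon.astype(str) + "_" + lat.astype(str)


def build_long_table(stack: RasterStack, mask: np.ndarray, value_name: str = "gpp") -> pd.DataFrame:
    """Convert a raster stack to a long table over masked-true pixels.

    One row per (masked pixel, layer) with a finite value; rows with
    missing values are dropped.  Longitude/latitude are cell centers.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} does not match layer shape {stack.shape}")
    lon, lat = stack.cell_centers()
    mlon, mlat = lon[mask], lat[mask]
    frames = []
    for ts, layer in zip(stack.timestamps, stack.layers):
        vals = layer[mask]
        keep = np.isfinite(vals)
        frames.append(
            pd.DataFrame(
                {
                    "longitude": mlon[keep],
                    "latitude": mlat[keep],
                    "date": ts,
                    value_name: vals[keep],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if table.empty:
        warnings.warn("no finite masked values in stack; long table is empty")
        return table
    table = table.sort_values(
        ["longitude", "latitude", "date"], kind="mergesort", ignore_index=True
    )
    return table


def add_calendar_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Split ``date`` into ``year``, ``month``, ``day`` columns."""
    table = table.copy()
    try:
        dates = pd.to_datetime(table["date"], format="mixed")
    except (ValueError, TypeError) as exc:
        # name the offending row for the caller
        for i, v in enumerate(table["date"]):
            try:
                pd.Timestamp(v)
            except (ValueError, TypeError):
                raise ValueError(f"unparseable date {v!r} at row {i}") from exc
        raise
    table["date"] = dates
    table["year"] = dates.dt.year.astype(int)
    table["month"] = dates.dt.month.astype(int)
    table["day"] = dates.dt.day.astype(int)
    return table


def label_event(table: pd.DataFrame, cutoff=DEFAULT_CUTOFF) -> pd.DataFrame:
    """Attach the two-level ``war`` factor: post iff date >= cutoff."""
    table = table.copy()
    cutoff = pd.Timestamp(cutoff)
    dates = pd.to_datetime(table["date"])
    table["war"] = np.where(dates >= cutoff, "post", "pre")
    return table


def aggregate_binned(
    table: pd.DataFrame,
    lon_decimals: int = 1,
    lat_decimals: int = 1,
    value: str = "gpp",
) -> pd.DataFrame:
    """Round pixel coordinates and aggregate duplicate rows with weights.

    A simple scalability aid: rows sharing the rounded (longitude,
    latitude) and date are averaged and carry a frequency ``weight``
    column that the model fit honours (sqrt-weight row scaling).
    Bit-exact agreement with the unbinned fit is not promised; on smooth
    fields the binned step estimate stays within a fraction of its SE.
    """
    tb = table.copy()
    tb["longitude"] = tb["longitude"].round(lon_decimals)
    tb["latitude"] = tb["latitude"].round(lat_decimals)
    agg = {value: (value, "mean"), "weight": (value, "size")}
    for c in ("year", "month", "day", "war"):
        if c in tb.columns:
            agg[c] = (c, "first")
    return tb.groupby(["longitude", "latitude", "date"], as_index=False).agg(**agg)


def read_long_table(path, cutoff=DEFAULT_CUTOFF) -> pd.DataFrame:
    """Read a long table CSV (longitude, latitude, date, gpp [, ...]).

    Calendar and event columns are (re)derived from ``date``.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    required = {"longitude", "latitude", "date", "gpp"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long table CSV is missing columns: {sorted(missing)}")
    table = table.dropna(subset=["gpp"]).reset_index(drop=True)
    table = add_calendar_columns(table)
    return label_event(table, cutoff)


def write_long_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    # repr-roundtrip floats so re-reading is bit-exact
    out.to_csv(path, index=False, float_format="%.17g")
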