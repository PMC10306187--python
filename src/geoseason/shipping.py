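"""Shipping route-density extraction around ports.

Monthly route-density rasters are reduced to one mean value per (port,
month) by averaging the cells whose centers fall within a great-circle
radius (default 20 km) of the port coordinates; per-year cumulative sums
and year-on-year percent change summarize activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import haversine_km
from .rasters import RasterStack

__all__ = [
    "PortZone",
    "DEFAULT_PORTS",
    "buffer_mean",
    "monthly_series",
    "cumulative_by_year",
    "percent_change",
    "read_ports_csv",
]


@dataclass
class PortZone:
    """Circular extraction zone around a port."""

    name: str
    longitude: float
    latitude: float
    radius_m: float = 20_000.0

    def __post_init__(self):
        if self.radius_m <= 0:
            raise ValueError("radius must be positive")


#: Port coordinates used for the Black Sea analysis (degrees WGS84).
DEFAULT_PORTS = (
    PortZone("Odesa", 30.74, 46.50),
    PortZone("Mariupol", 38.14, 46.97),
    PortZone("Constanta", 28.74, 44.07),
)


def buffer_mean(layer: np.ndarray, stack: RasterStack, zone: PortZone) -> float:
    """Unweighted mean of cells with centers within the zone radius.

    Missing (NaN) cells are excluded; an error is raised if no cell center
    falls inside the buffer.
    """
    lon, lat = stack.cell_centers()
    ext = stack.extent()
    if not (ext[0] <= zone.longitude <= ext[1] and ext[2] <= zone.latitude <= ext[3]):
        raise ValueError(f"zone {zone.name!r} lies outside the raster extent {ext}")
    d = haversine_km(
        np.column_stack([lon.ravel(), lat.ravel()]),
        np.array([[zone.longitude, zone.latitude]]),
    )[:, 0]
    inside = d <= zone.radius_m / 1000.0
    vals = np.asarray(layer, dtype=float).ravel()[inside]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError(f"no finite cells within {zone.radius_m} m of zone {zone.name!r}")
    return float(vals.mean())


def monthly_series(stack: RasterStack, zones) -> pd.DataFrame:
    """Per-(zone, month) mean density with calendar columns.

    Rows are ordered deterministically by (port, date).
    """
    rows = []
    for zone in zones:
        for ts, layer in zip(stack.timestamps, stack.layers):
            rows.append(
                {
                    "port": zone.name,
                    "date": ts,
                    "year": ts.year,
                    "month": ts.month,
                    "day": ts.day,
                    "density": buffer_mean(layer, stack, zone),
                }
            )
    out = pd.DataFrame(rows).sort_values(["port", "date"], ignore_index=True)
    return out


def cumulative_by_year(series: pd.DataFrame) -> pd.DataFrame:
    """Within-year cumulative sum of density per port (resets each January)."""
    out = series.sort_values(["port", "date"]).copy()
    out["cumulative"] = out.groupby(["port", "year"])["density"].cumsum()
    return out.reset_index(drop=True)


def percent_change(
    series: pd.DataFrame,
    port: str,
    year_a: int,
    year_b: int,
    compare_month: int | None = None,
    reference_month: int | None = None,
) -> float:
    """Percent change in cumulative density from year_a to year_b.

    100 * (cum_b[compare_month] - cum_a[compare_month]) / cum_a[reference_month];
    negative = decline.  By default both months are the last month common
    to both years' series for the port.
    """
    if "cumulative" not in series.columns:
        series = cumulative_by_year(series)
    sub = series[series["port"] == port]
    if sub.empty:
        raise ValueError(f"no rows for port {port!r}")
    a = sub[sub["year"] == year_a].set_index("month")["cumulative"]
    b = sub[sub["year"] == year_b].set_index("month")["cumulative"]
    if a.empty or b.empty:
        raise ValueError(f"port {port!r} lacks data for {year_a} or {year_b}")
    if compare_month is None:
        compare_month = int(min(a.index.max(), b.index.max()))
    if reference_month is None:
        reference_month = compare_month
    for m, s, yr in ((compare_month, a, year_a), (compare_month, b, year_b), (reference_month, a, year_a)):
        if m not in s.index:
            raise ValueError(f"month {m} missing for port {port!r} in {yr}")
    ref = float(a.loc[reference_month])
    if ref == 0:
        raise ValueError("reference cumulative value is zero")
    return 100.0 * (float(b.loc[compare_month]) - float(a.loc[compare_month])) / ref


def read_ports_csv(path, radius_m: float = 20_000.0):
    """Read a port table CSV with name, lon(gitude), lat(itude) columns."""
    df = pd.read_csv(path)
    cols = {c.lower()[:3]: c for c in df.columns}
    name_c = cols.get("nam", df.columns[0])
    lon_c = cols.get("lon")
    lat_c = cols.get("lat")
    if lon_c is None or lat_c is None:
        raise ValueError("port CSV needs name, lon, lat columns")
    return [
        PortZone(str(r[name_c]), float(r[lon_c]), float(r[lat_c]), radius_m)
        for _, r in df.iterrows()
    ]
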