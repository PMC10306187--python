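"""Minimal raster container and plain-text grid I/O.

A :class:`RasterStack` carries a list of 2-D arrays sharing one geotransform,
with one timestamp per layer.  Grids are stored north-up: row 0 is the
northernmost row.  Persistence uses the ESRI ASCII grid format (one ``.asc``
file per layer, date encoded in the filename), which keeps fixtures and
outputs text-only and readable by standard GIS tooling.
"""

from __future__ import annotations

import glob as _glob
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RasterStack", "read_ascii_grid", "write_ascii_grid", "stack_from_files"]

_NODATA = -9999.0


@dataclass
class RasterStack:
    """Stack of co-registered 2-D layers with per-layer timestamps.

    Parameters
    ----------
    layers
        List of 2-D float arrays, all the same shape; NaN marks missing cells.
    x_origin, y_origin
        Longitude of the *left edge* of the first column and latitude of the
        *top edge* of the first row, in degrees (WGS84 assumed).
    dx, dy
        Cell width (positive, degrees east) and cell height (positive,
        degrees; rows run north to south).
    timestamps
        One ``pandas.Timestamp``-coercible value per layer, strictly
        increasing.
    """

    layers: list
    x_origin: float
    y_origin: float
    dx: float
    dy: float
    timestamps: list = field(default_factory=list)
    crs: str = "EPSG:4326"

    def __post_init__(self):
        self.layers = [np.asarray(a, dtype=float) for a in self.layers]
        if not self.layers:
            raise ValueError("RasterStack needs at least one layer")
        shape = self.layers[0].shape
        for a in self.layers:
            if a.ndim != 2 or a.shape != shape:
                raise ValueError("all layers must share one 2-D shape")
        if len(self.timestamps) != len(self.layers):
            raise ValueError("one timestamp per layer required")
        self.timestamps = [pd.Timestamp(t) for t in self.timestamps]
        if any(b <= a for a, b in zip(self.timestamps, self.timestamps[1:])):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def shape(self):
        return self.layers[0].shape

    def cell_centers(self):
        """Longitude and latitude of every cell center as 2-D arrays."""
        ny, nx = self.shape
        lon = self.x_origin + (np.arange(nx) + 0.5) * self.dx
        lat = self.y_origin - (np.arange(ny) + 0.5) * self.dy
        return np.meshgrid(lon, lat)

    def extent(self):
        """(lon_min, lon_max, lat_min, lat_max) of the outer cell edges."""
        ny, nx = self.shape
        return (
            self.x_origin,
            self.x_origin + nx * self.dx,
            self.y_origin - ny * self.dy,
            self.y_origin,
        )


def write_ascii_grid(path: str, grid: np.ndarray, x_origin: float, y_origin: float, cellsize: float) -> None:
    """Write one layer as an ESRI ASCII grid (square cells only)."""
    grid = np.asarray(grid, dtype=float)
    ny, nx = grid.shape
    out = np.where(np.isnan(grid), _NODATA, grid)
    header = (
        f"ncols {nx}\nnrows {ny}\n"
        f"xllcorner {x_origin!r}\nyllcorner {y_origin - ny * cellsize!r}\n"
        f"cellsize {cellsize!r}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str):
    """Read an ESRI ASCII grid; returns (grid, x_origin, y_origin, cellsize)."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # headers are optional beyond the first four
                break
        fh.seek(pos)
        grid = np.loadtxt(fh, ndmin=2)
    ny, nx = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (ny, nx):
        raise ValueError(f"{path}: grid shape {grid.shape} does not match header ({ny}, {nx})")
    nodata = header.get("nodata_value", _NODATA)
    grid = np.where(grid == nodata, np.nan, grid)
    cs = header["cellsize"]
    y_origin = header["yllcorner"] + ny * cs
    return grid, header["xllcorner"], y_origin, cs


def stack_from_files(pattern: str, date_regex: str = r"(\d{4}-\d{2}-\d{2})") -> RasterStack:
    """Build a stack from ``.asc`` files whose names carry an ISO date.

    Files matching *pattern* are ordered by the date parsed from each
    filename with *date_regex* (first capture group).
    """
    paths = sorted(_glob.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no rasters match {pattern!r}")
    dated = []
    for p in paths:
        m = re.search(date_regex, os.path.basename(p))
        if not m:
            raise ValueError(f"cannot parse a date from filename {p!r}")
        dated.append((pd.Timestamp(m.group(1)), p))
    dated.sort()
    grids, geo = [], None
    for _, p in dated:
        grid, x0, y0, cs = read_ascii_grid(p)
        if geo is None:
            geo = (x0, y0, cs)
        elif not np.allclose(geo, (x0, y0, cs)):
            raise ValueError(f"{p}: geotransform differs from first layer")
        grids.append(grid)
    x0, y0, cs = geo
    return RasterStack(grids, x0, y0, cs, cs, timestamps=[t for t, _ in dated])
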