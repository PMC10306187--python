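"""Synthetic data with known truth for every stage of the pipeline.

``simulate_gpp`` generates a long table whose mean structure mirrors the
additive model — a smooth spatial field (sum of Gaussian bumps), a cyclic
12-month seasonal curve, an optional smooth inter-annual trend and
space-time interaction, and an additive step after a cutoff date — with
per-pixel AR(1) temporal noise plus white observation noise.  The truth
used in generation is returned so recovery can be tested exactly.

``simulate_shipping`` builds monthly route-density rasters with
Gaussian-ridge corridors between ports and optional blackout windows where
activity around named ports drops to zero.

Default scene (the package's study conditions): a 16 x 16 pixel grid
observed twice a month for three years (18,432 rows), seasonal amplitude
1.5 gC/m^2 peaking mid-year, no inter-annual trend, a -0.247 gC/m^2 step
at a calendar-year boundary, AR(1) rho = 0.3, observation noise 0.5.
The year-boundary cutoff (rather than late February) keeps the injected
step identifiable in the event model, whose by-level seasonal smooths
otherwise absorb part of a mid-season step; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import haversine_km
from .data_model import add_calendar_columns, label_event
from .rasters import RasterStack

__all__ = ["SimConfig", "SyntheticTruth", "simulate_gpp", "simulate_shipping"]


@dataclass
class SimConfig:
    """Scene description for the synthetic GPP generator."""

    nx: int = 16
    ny: int = 16
    lon_range: tuple = (30.0, 33.0)
    lat_range: tuple = (46.0, 49.0)
    years: tuple = (2020, 2022)  # inclusive
    epochs_per_month: int = 2
    base_level: float = 3.0  # gC/m^2 per 8-day composite, cropland scale
    seasonal_amplitude: float = 1.5
    seasonal_phase: float = 7.0  # month of seasonal peak
    trend_slope: float = 0.0  # gC/m^2 per year
    bumps: tuple = (
        (30.8, 46.8, 0.9, 1.0),  # (lon, lat, width_deg, height)
        (32.2, 48.2, 0.7, -0.8),
    )
    interaction_amplitude: float = 0.0
    delta: float = -0.247  # additive step after cutoff
    cutoff: str = "2022-01-01"
    rho: float = 0.3
    ar_sd: float = 0.3  # marginal sd of the AR(1) component
    sigma: float = 0.5  # white observation noise sd
    seed: int = 20230628

    def __post_init__(self):
        if self.sigma < 0 or self.ar_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")
        if self.lon_range[0] >= self.lon_range[1] or self.lat_range[0] >= self.lat_range[1]:
            raise ValueError("empty spatial extent")


@dataclass
class SyntheticTruth:
    """Exact components used in generation."""

    spatial: np.ndarray  # per-pixel mean surface (ny x nx)
    seasonal: np.ndarray  # value at months 1..12
    trend: dict  # year -> value
    delta: float
    rho: float
    base_level: float
    lon: np.ndarray = field(default=None)
    lat: np.ndarray = field(default=None)


def _seasonal_value(month, cfg: SimConfig):
    # integer-month cosine: sums to zero over a full year
    return cfg.seasonal_amplitude * np.cos(2 * np.pi * (np.asarray(month) - cfg.seasonal_phase) / 12.0)


def _spatial_field(lon, lat, cfg: SimConfig):
    z = np.full(np.broadcast(lon, lat).shape, cfg.base_level, dtype=float)
    for cx, cy, w, h in cfg.bumps:
        z = z + h * np.exp(-((lon - cx) ** 2 + (lat - cy) ** 2) / (2 * w**2))
    return z


def simulate_gpp(cfg: SimConfig | None = None):
    """Generate a (LongTable, SyntheticTruth) pair under *cfg*.

    value = spatial(s) + seasonal(m) + trend(y) + interaction
            + delta * 1[date >= cutoff] + AR1 noise + white noise.
    """
    cfg = cfg or SimConfig()
    rs = np.random.default_rng(cfg.seed)
    nx, ny = cfg.nx, cfg.ny
    lon1 = cfg.lon_range[0] + (np.arange(nx) + 0.5) * (cfg.lon_range[1] - cfg.lon_range[0]) / nx
    lat1 = cfg.lat_range[0] + (np.arange(ny) + 0.5) * (cfg.lat_range[1] - cfg.lat_range[0]) / ny
    LON, LAT = np.meshgrid(lon1, lat1)
    spatial = _spatial_field(LON, LAT, cfg)

    years = np.arange(cfg.years[0], cfg.years[1] + 1)
    mid_year = years.mean()
    day_grid = np.linspace(1, 28, cfg.epochs_per_month + 1)[:-1].round().astype(int) + 2
    dates = [
        pd.Timestamp(int(y), int(m), int(d))
        for y in years
        for m in range(1, 13)
        for d in day_grid
    ]
    n_t = len(dates)
    months = np.array([d.month for d in dates])
    yrs = np.array([d.year for d in dates])
    cutoff = pd.Timestamp(cfg.cutoff)
    post = np.array([d >= cutoff for d in dates], dtype=float)

    seasonal_t = _seasonal_value(months, cfg)
    trend_t = cfg.trend_slope * (yrs - mid_year)
    n_pix = nx * ny
    # temporal mean per epoch, shared across pixels apart from the surface
    mu_t = seasonal_t + trend_t + cfg.delta * post

    if cfg.interaction_amplitude:
        inter = cfg.interaction_amplitude * np.outer(
            (LON.ravel() - LON.mean()) / max(np.ptp(LON), 1e-9), (yrs - mid_year)
        )
    else:
        inter = 0.0

    # AR(1) component per pixel, marginal sd = ar_sd
    noise = np.zeros((n_pix, n_t))
    if cfg.ar_sd > 0:
        innov_sd = cfg.ar_sd * np.sqrt(1 - cfg.rho**2)
        e = rs.normal(0.0, 1.0, size=(n_pix, n_t))
        noise[:, 0] = cfg.ar_sd * e[:, 0]
        for t in range(1, n_t):
            noise[:, t] = cfg.rho * noise[:, t - 1] + innov_sd * e[:, t]
    if cfg.sigma > 0:
        noise = noise + rs.normal(0.0, cfg.sigma, size=(n_pix, n_t))

    values = spatial.ravel()[:, None] + mu_t[None, :] + inter + noise

    table = pd.DataFrame(
        {
            "longitude": np.repeat(LON.ravel(), n_t),
            "latitude": np.repeat(LAT.ravel(), n_t),
            "date": np.tile(pd.to_datetime(dates), n_pix),
            "gpp": values.ravel(),
        }
    )
    table = add_calendar_columns(table)
    table = label_event(table, cutoff)
    truth = SyntheticTruth(
        spatial=spatial,
        seasonal=_seasonal_value(np.arange(1, 13), cfg),
        trend={int(y): float(cfg.trend_slope * (y - mid_year)) for y in years},
        delta=cfg.delta,
        rho=cfg.rho,
        base_level=cfg.base_level,
        lon=lon1,
        lat=lat1,
    )
    return table, truth


# ---------------------------------------------------------------------------
# shipping scenes


def _segment_distance_km(lon, lat, a, b):
    """Great-circle-ish distance from grid points to segment a-b (km).

    Uses an equirectangular projection about the segment's mean latitude —
    adequate at corridor scale — then exact point-segment distance.
    """
    lat0 = np.deg2rad((a[1] + b[1]) / 2.0)
    kx = 111.32 * np.cos(lat0)
    ky = 110.57
    px, py = (lon - a[0]) * kx, (lat - a[1]) * ky
    vx, vy = (b[0] - a[0]) * kx, (b[1] - a[1]) * ky
    vv = vx**2 + vy**2
    t = np.clip((px * vx + py * vy) / max(vv, 1e-12), 0.0, 1.0)
    return np.sqrt((px - t * vx) ** 2 + (py - t * vy) ** 2)


def simulate_shipping(
    months,
    ports,
    corridors,
    blackout_window=None,
    blackout_ports=(),
    blackout_radius_km: float = 60.0,
    seed: int = 20230628,
    grid=(25.5, 43.5, 40.1, 48.1),
    cellsize: float = 0.05,
    noise_cv: float = 0.1,
) -> RasterStack:
    """Monthly route-density rasters with corridor structure.

    ``corridors`` is a list of (port_name_a, port_name_b, intensity,
    width_km).  ``blackout_window`` is a (start, end) date pair (month
    resolution, inclusive); within it, all density within
    ``blackout_radius_km`` of each named blackout port is set to zero.
    Densities are non-negative everywhere.
    """
    rs = np.random.default_rng(seed)
    by_name = {p.name: p for p in ports}
    lon_min, lon_max, lat_min, lat_max = grid
    nx = int(round((lon_max - lon_min) / cellsize))
    ny = int(round((lat_max - lat_min) / cellsize))
    lon = lon_min + (np.arange(nx) + 0.5) * cellsize
    lat = lat_max - (np.arange(ny) + 0.5) * cellsize
    LON, LAT = np.meshgrid(lon, lat)

    base = np.zeros((ny, nx))
    ridges = []
    for na, nb, intensity, width in corridors:
        a, b = by_name[na], by_name[nb]
        d = _segment_distance_km(LON, LAT, (a.longitude, a.latitude), (b.longitude, b.latitude))
        ridges.append(intensity * np.exp(-(d**2) / (2 * width**2)))
        base += ridges[-1]

    months = [pd.Timestamp(m) for m in months]
    if blackout_window is not None:
        b0, b1 = pd.Timestamp(blackout_window[0]), pd.Timestamp(blackout_window[1])
    layers = []
    for ts in months:
        layer = base * np.exp(rs.normal(0.0, noise_cv)) if noise_cv > 0 else base.copy()
        if blackout_window is not None and b0 <= ts <= b1:
            for name in blackout_ports:
                p = by_name[name]
                d = haversine_km(
                    np.column_stack([LON.ravel(), LAT.ravel()]),
                    np.array([[p.longitude, p.latitude]]),
                )[:, 0].reshape(ny, nx)
                layer = np.where(d <= blackout_radius_km, 0.0, layer)
        layers.append(np.maximum(layer, 0.0))
    return RasterStack(layers, lon_min, lat_max, cellsize, cellsize, timestamps=months)
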