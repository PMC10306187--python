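"""Effect curves, prediction surfaces, the step-change test, tercile maps.

"Summed effect" follows the usual additive-model plotting convention: the
linear predictor is evaluated over a grid of the covariate of interest with
every other covariate held at a reference value (medians; the event factor
at a chosen level), and the standard error comes from the posterior
covariance of the coefficients through the delta method (here exact, since
the predictor is linear in the coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import FittedGAM

__all__ = [
    "EffectCurve",
    "SpatialPrediction",
    "effect_curve",
    "predict_surface",
    "event_effect_test",
    "bivariate_terciles",
    "DEFAULT_PALETTE",
]

#: 3x3 bivariate palette, estimate terciles (columns, green) x SE terciles
#: (rows, purple); class 1 = low estimate / low SE ... class 9 = high/high.
DEFAULT_PALETTE = [
    "#e8e8e8", "#b5e3b5", "#52c252",
    "#cdb4d6", "#a3b1a9", "#3e9e63",
    "#9e64c8", "#7a6fa0", "#2b5c54",
]


@dataclass
class EffectCurve:
    grid: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    term: str
    level: str | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"grid": self.grid, "estimate": self.estimate, "se": self.se})
        out["term"] = self.term
        if self.level is not None:
            out["level"] = self.level
        return out


@dataclass
class SpatialPrediction:
    longitude: np.ndarray
    latitude: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    tercile_class: np.ndarray
    hex_color: np.ndarray
    inside_hull: np.ndarray
    level: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "longitude": self.longitude,
                "latitude": self.latitude,
                "estimate": self.estimate,
                "se": self.se,
                "tercile_class": self.tercile_class,
                "hex": self.hex_color,
                "inside_hull": self.inside_hull,
                "level": self.level,
            }
        )


def _reference_frame(fit: FittedGAM, n: int, level: str | None) -> pd.DataFrame:
    refs = fit.design.table_refs
    data = {k: np.full(n, v) for k, v in refs.items()}
    if fit.has_factor:
        data["war"] = np.full(n, level if level is not None else "pre", dtype=object)
    return pd.DataFrame(data)


def effect_curve(
    fit: FittedGAM,
    term: str,
    grid=None,
    level: str | None = None,
    training_range: tuple | None = None,
) -> EffectCurve:
    """Summed effect of one covariate over a grid, with standard errors.

    ``term`` is a covariate name ("year", "month", ...).  Grid points
    outside the training range are linearly extrapolated with a warning.
    """
    covs = {c for t in fit.design.terms for c in t.covariates}
    if term not in covs:
        raise ValueError(f"no smooth term involves covariate {term!r}; have {sorted(covs)}")
    if grid is None:
        lo, hi = training_range or (None, None)
        if lo is None:
            ref = fit.design.table_refs[term]
            lo, hi = ref - 1, ref + 1
        grid = np.linspace(lo, hi, 100)
    grid = np.asarray(grid, dtype=float)
    if training_range is not None and (grid.min() < training_range[0] or grid.max() > training_range[1]):
        warnings.warn(f"grid extends beyond the training range of {term!r}; extrapolating linearly")
    newdata = _reference_frame(fit, len(grid), level)
    newdata[term] = grid
    est, se = fit.predict(newdata, se=True)
    return EffectCurve(grid=grid, estimate=est, se=se, term=term, level=level)


def predict_surface(
    fit: FittedGAM,
    lon_grid,
    lat_grid,
    level: str | None = None,
    training_coords: np.ndarray | None = None,
    palette=None,
) -> SpatialPrediction:
    """Linear-predictor estimate and SE on a lon/lat grid.

    Grid nodes outside the convex hull of the training pixels are flagged
    (``inside_hull``); tercile classes and hex colors are attached for
    bivariate estimate/uncertainty mapping.
    """
    lon_grid = np.asarray(lon_grid, dtype=float)
    lat_grid = np.asarray(lat_grid, dtype=float)
    LON, LAT = np.meshgrid(lon_grid, lat_grid)
    lon, lat = LON.ravel(), LAT.ravel()
    newdata = _reference_frame(fit, len(lon), level)
    newdata["longitude"] = lon
    newdata["latitude"] = lat
    est, se = fit.predict(newdata, se=True)
    inside = np.ones(len(lon), dtype=bool)
    if training_coords is not None and len(training_coords) >= 3:
        from scipy.spatial import Delaunay

        tri = Delaunay(np.asarray(training_coords, dtype=float))
        inside = tri.find_simplex(np.column_stack([lon, lat])) >= 0
    classes, hexes = bivariate_terciles(est, se, palette)
    return SpatialPrediction(
        longitude=lon, latitude=lat, estimate=est, se=se,
        tercile_class=classes, hex_color=hexes, inside_hull=inside, level=level,
    )


def event_effect_test(fit: FittedGAM):
    """Wald test of the pre/post step coefficient.

    Returns (estimate, SE, t, p); two-sided p from the t distribution with
    the fit's residual degrees of freedom (normal approximation once the
    residual dof exceeds 1e4).
    """
    est = fit.war_coefficient  # raises if no factor
    se = fit.war_se
    t = est / se
    df = fit.residual_df
    if df > 1e4:
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df)
    return est, se, t, float(p)


def _tercile_index(x: np.ndarray) -> np.ndarray:
    """0/1/2 tercile index from the sample's own terciles, ties to lower."""
    cuts = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    return np.searchsorted(cuts, x, side="left")


def bivariate_terciles(estimates, ses, palette=None):
    """Map (estimate, SE) pairs to 9 bivariate classes and hex colors.

    Terciles are computed independently from each plotted sample; class =
    3*(SE tercile) + (estimate tercile) + 1, so classes 1..3 are the
    lowest-uncertainty row.
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if estimates.shape != ses.shape:
        raise ValueError("estimates and ses must have the same shape")
    palette = list(palette) if palette is not None else DEFAULT_PALETTE
    if len(palette) != 9:
        raise ValueError("palette must have exactly 9 colors")
    ei = _tercile_index(estimates)
    si = _tercile_index(ses)
    classes = 3 * si + ei + 1
    hexes = np.asarray(palette, dtype=object)[classes - 1]
    return classes, hexes
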