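"""Validation of the model's annual trend against external production data.

The fitted year effect is compared with an annual crop-production series
(tonnes) by the sequence used in practice for such checks: Shapiro-Wilk
normality tests on both series, then a one-sided Pearson correlation test
for a positive relationship.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .gam import FittedGAM
from .inference import effect_curve

__all__ = [
    "shapiro_wilk",
    "pearson_one_sided",
    "annual_effect_series",
    "read_production_csv",
    "DEFAULT_CROPS",
    "validate_against_production",
]

DEFAULT_CROPS = ("Barley", "Maize (corn)", "Wheat", "Rape or colza seed", "Potatoes", "Sunflower seed")


def shapiro_wilk(x):
    """Shapiro-Wilk normality test; returns (W, p).

    Uses the standard algorithmic approximation of the test coefficients
    and p-value (as implemented in scipy).  Requires 3 <= n <= 5000 and a
    non-constant sample.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: Shapiro-Wilk undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def pearson_one_sided(x, y, alternative: str = "greater"):
    """One-sided Pearson correlation test; returns (r, t, df, p).

    r is the sample correlation, df = n - 2, t = r sqrt(df / (1 - r^2)),
    and p comes from the corresponding tail of the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    r_ = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    if alternative == "greater":
        p = stats.t.sf(t, df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    elif alternative == "two-sided":
        p = 2 * stats.t.sf(abs(t), df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return r, float(t), df, float(p)


def annual_effect_series(fit: FittedGAM, years=None, centered: bool = False) -> pd.DataFrame:
    """Year-effect series: the summed year effect at each observed year.

    Returns a frame with ``year`` and ``value`` columns.  ``centered=True``
    subtracts the series mean (useful when correlating shapes rather than
    levels; the correlation itself is invariant to the shift).
    """
    if years is None:
        ref = fit.design.table_refs.get("year")
        if ref is None:
            raise ValueError("fit has no year covariate; pass years explicitly")
        raise ValueError("pass the observed years explicitly (e.g. table['year'].unique())")
    years = np.sort(np.unique(np.asarray(years, dtype=int)))
    curve = effect_curve(fit, "year", grid=years.astype(float))
    vals = curve.estimate - curve.estimate.mean() if centered else curve.estimate
    return pd.DataFrame({"year": years, "value": vals, "se": curve.se})


def read_production_csv(path, crops=DEFAULT_CROPS) -> pd.DataFrame:
    """Read an annual production CSV; returns year / tonnes totals.

    Accepts either a plain (year, tonnes) table or a FAOSTAT-style export
    with Area/Item/Year/Value columns, summing Value over the configured
    crop list per year.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "year" in cols and "tonnes" in cols:
        out = df[[cols["year"], cols["tonnes"]]].rename(
            columns={cols["year"]: "year", cols["tonnes"]: "tonnes"}
        )
    elif "year" in cols and "value" in cols:
        if "item" in cols and crops is not None:
            df = df[df[cols["item"]].isin(crops)]
        out = (
            df.groupby(cols["year"], as_index=False)[cols["value"]]
            .sum()
            .rename(columns={cols["year"]: "year", cols["value"]: "tonnes"})
        )
    else:
        raise ValueError("production CSV needs (year, tonnes) or FAOSTAT Year/Value columns")
    out["year"] = out["year"].astype(int)
    return out.sort_values("year", ignore_index=True)


def validate_against_production(fit: FittedGAM, production: pd.DataFrame, years=None) -> dict:
    """Full validation sequence; returns a dict of test results.

    Normality of both annual series is checked with Shapiro-Wilk, then a
    one-sided Pearson test for a positive correlation is run on the years
    common to both series.  Both the intercept-inclusive and centered year
    effects are reported (the correlation is identical).
    """
    if years is None:
        years = production["year"].to_numpy()
    eff = annual_effect_series(fit, years=years)
    merged = pd.merge(eff, production, on="year", how="inner")
    if len(merged) < 3:
        raise ValueError("fewer than 3 overlapping years between model and production series")
    w_eff, p_eff = shapiro_wilk(merged["value"])
    w_prod, p_prod = shapiro_wilk(merged["tonnes"])
    r, t, df, p = pearson_one_sided(merged["value"], merged["tonnes"], "greater")
    return {
        "n_years": int(len(merged)),
        "shapiro_effect": {"W": w_eff, "p": p_eff},
        "shapiro_production": {"W": w_prod, "p": p_prod},
        "pearson": {"r": r, "t": t, "df": df, "p": p},
        "effect_series": merged[["year", "value"]].to_dict("list"),
        "effect_series_centered": {
            "year": merged["year"].tolist(),
            "value": (merged["value"] - merged["value"].mean()).tolist(),
        },
    }
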