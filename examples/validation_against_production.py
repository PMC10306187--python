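"""Validate the fitted annual trend against an annual production series.

Fits the trend model to an 11-year synthetic scene (2010-2020), builds a
production series (tonnes) positively tied to the true trend, and runs the
validation sequence: Shapiro-Wilk normality on both annual series, then a
one-sided Pearson test for a positive correlation (df = n - 2 = 9).
"""

import numpy as np
import pandas as pd

from geoseason import ModelConfig, SimConfig, simulate_gpp, validate_against_production
from geoseason.gam import fit_eq1

cfg = SimConfig(nx=6, ny=6, years=(2010, 2020), epochs_per_month=1,
                trend_slope=0.1, delta=0.0, cutoff="2030-01-01", seed=21)
table, truth = simulate_gpp(cfg)
fit = fit_eq1(table, ModelConfig(space_k=15, include_tensors=False))

rs = np.random.default_rng(22)
years = np.sort(table["year"].unique())
production = pd.DataFrame(
    {"year": years,
     "tonnes": 50e6 + 30e6 * np.array([truth.trend[y] for y in years])
     + rs.normal(0, 1.5e6, len(years))}
)

result = validate_against_production(fit, production)
print(f"years compared       : {result['n_years']}")
print(f"Shapiro-Wilk (model) : W = {result['shapiro_effect']['W']:.3f}, "
      f"p = {result['shapiro_effect']['p']:.3f}")
print(f"Shapiro-Wilk (prod.) : W = {result['shapiro_production']['W']:.3f}, "
      f"p = {result['shapiro_production']['p']:.3f}")
pr = result["pearson"]
print(f"one-sided Pearson    : r = {pr['r']:.3f}, t = {pr['t']:.2f}, "
      f"df = {pr['df']}, p = {pr['p']:.4f}")
print("\nA large r at small p confirms the model's annual effect tracks the")
print("external production series; non-significant Shapiro p-values support")
print("the normality assumption behind the correlation test.")
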