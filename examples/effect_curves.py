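"""Extract summed effect curves: annual trend and pre/post seasonal shape.

Fits the trend model to a scene with a 0.1 gC/m^2-per-year trend and the
event model to a scene with a post-period seasonal shift, then prints the
year curve and the month curves per period with standard errors.
"""

import numpy as np

from geoseason import (
    ModelConfig,
    SimConfig,
    effect_curve,
    fit_eq1,
    fit_eq2,
    simulate_gpp,
)

# --- annual trend -----------------------------------------------------------
cfg = SimConfig(nx=8, ny=8, years=(2018, 2022), epochs_per_month=1,
                trend_slope=0.1, delta=0.0, seed=11)
table, truth = simulate_gpp(cfg)
fit = fit_eq1(table, ModelConfig(space_k=20, include_tensors=False))
years = np.sort(table["year"].unique()).astype(float)
curve = effect_curve(fit, "year", grid=years)
print("summed effect of year (truth slope 0.1/yr):")
for y, e, s in zip(years, curve.estimate, curve.se):
    print(f"  {int(y)}: {e:.3f} +- {s:.3f}")

# --- seasonal curves pre/post ----------------------------------------------
table2, _ = simulate_gpp(SimConfig(nx=8, ny=8, seed=12))
fit2 = fit_eq2(table2, ModelConfig(space_k=20, include_tensors=False))
grid = np.arange(1.0, 13.0)
pre = effect_curve(fit2, "month", grid=grid, level="pre")
post = effect_curve(fit2, "month", grid=grid, level="post")
print("\nsummed effect of month (pre | post), gC/m^2:")
for m in range(12):
    print(f"  month {m + 1:2d}: {pre.estimate[m]:6.3f} | {post.estimate[m]:6.3f}")
print("\nThe post curve sits ~0.25 gC/m^2 below the pre curve (the injected")
print("step) while sharing its seasonal shape; a mid-year peak reflects the")
print("generated growing season.")
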