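# geoseason

Spatio-temporal additive modelling of gridded cropland productivity, with
pre/post-event step-change inference, validation against annual production
series, and shipping-activity extraction around ports.

## Who this is for

Analysts monitoring cropland condition from satellite-derived Gross
Primary Productivity (GPP, gC/m² per 8-day composite) who need fast,
uncertainty-quantified answers to questions like *"did mean productivity
change after a disruptive event, and by how much?"* — alongside a view of
export logistics from monthly shipping route-density rasters. Everything
is testable end to end on synthetic data with known truth; no downloads
are required.

## The model

GPP observations `z_i` at pixel `s_i`, month `m_i`, year `y_i` follow a
Gaussian additive model

```
z_i ~ N(mu_i, phi)
mu_i = beta + f1(y_i) + f2(m_i) + f3(s_i) + f4(y_i, m_i) + f5(s_i, y_i)   (trend model)
mu_i = beta + w_i + f1(m_i) w_i + f2(s_i) w_i + f3(s_i, m_i) w_i          (event model)
```

with a cubic regression spline for year (k = number of years), a cyclic
cubic spline for month (k = 12), a low-rank Matérn(3/2) Gaussian-process
smooth for space (k = 50), tensor-product interactions, and a two-level
pre/post factor `w_i` whose by-level smooth copies absorb per-period
seasonal and spatial structure. Smoothing parameters are chosen by REML;
within-pixel temporal dependence is handled by an AR(1) working
correlation (plug-in lag-1 ρ, whitening, refit). The coefficient on the
"post" level is the additive step in mean GPP after the cutoff, tested by
a Wald t. See `docs/methods.md` for the full account.

## Worked example

```bash
python examples/step_change_recovery.py
```

```
scene: 18432 observations, injected step -0.247 gC/m^2
estimated step : -0.2556 gC/m^2 (SE 0.0095)
Wald test      : t = -26.88, p = 3.90e-159
AR(1) rho      : 0.062 (residual lag-1 of the mixed noise ~ 0.08)
effective dof  : 64.4 of 72 coefficients
```

The generator injected a −0.247 gC/m² step at 2022-01-01 into a scene
with seasonal, spatial and AR(1) structure; the event model recovers it
within two standard errors, and the large negative t is how a genuine
post-event productivity drop surfaces. The other examples cover effect
curves (`examples/effect_curves.py`), validation against a production
series (`examples/validation_against_production.py` — prints the
one-sided Pearson r, t, df = 9, p sequence), and shipping extraction with
a blackout window (`examples/shipping_activity.py`).

The same stages are scriptable from the shell:

```bash
geoseason simulate gpp --seed 1 -o table.csv
geoseason fit --table table.csv --model eq2 --cutoff 2022-01-01 -o fit.json
geoseason effects --table table.csv --model eq2 --term month --by-war -o curves.csv
```

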