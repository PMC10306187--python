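# Methods

## Model

The package decomposes a gridded time series of cropland Gross Primary
Productivity (GPP, gC/m² per 8-day composite) into additive smooth
components. For observation *z*ᵢ at pixel *s*ᵢ = (lon, lat), month *m*ᵢ and
year *y*ᵢ,

    z_i ~ N(mu_i, phi)
    mu_i = beta + f1(y_i) + f2(m_i) + f3(s_i) + f4(y_i, m_i) + f5(s_i, y_i)

is the **trend model**, and

    mu_i = beta + w_i + f1(m_i) w_i + f2(s_i) w_i + f3(s_i, m_i) w_i

is the **event model**, where *w*ᵢ is a two-level pre/post factor
(treatment coded, "pre" the reference) and the *f·w* products are
factor-"by" smooth copies, one per level. The coefficient on the "post"
dummy is the additive step in mean GPP after the cutoff date, after
seasonal and spatial variation per period has been absorbed by the
by-level smooths; it is the quantity the event model exists to estimate,
reported with a Wald *t* and *p* from the residual degrees of freedom.

## Bases and penalties

* **Year**: cardinal natural cubic regression spline, basis dimension k =
  number of unique years, knots at quantiles of the unique years.
  Coefficients are the spline's values at the knots; the penalty is the
  exact integrated squared second derivative, assembled from the banded
  natural-spline identities (B gamma = D beta, S = D'B⁻¹D).
* **Month**: cyclic cubic regression spline, k = 12, knots evenly spaced
  over [1, 13) with period 12, so value, first and second derivative match
  across the December→January wrap by construction.
* **Space**: low-rank Gaussian-process smooth. k knots (default 50) are
  placed by farthest-point design over the observed pixels; a Matérn(3/2)
  kernel with unit marginal variance is evaluated at the knots; data are
  projected by the Nyström construction onto the knot eigenbasis, scaled
  so the prior covariance of the fitted field is K_nm K_mm⁻¹ K_mn. The
  penalty is diagonal in the inverse kernel eigenvalues. Distances are
  great-circle km by default (a "degrees" mode is available); the default
  range is half the maximum inter-point distance. Eigenvalues below
  1e-10 of the maximum are truncated, which can reduce the effective basis
  dimension below k.
* **Interactions**: tensor products of already-centered marginal bases
  (row-wise Kronecker), with one smoothing parameter per margin
  (S_a ⊗ I and I ⊗ S_b). Centering the marginals first excludes the main
  effects from the interaction's span. The spatial margin inside tensors
  is truncated to k = 20 to keep interaction blocks tractable.
* **Identifiability**: every smooth is constrained to sum to zero over the
  training rows (null-space projection of the column-sum constraint via
  QR). By-level copies share the constraint computed on all rows and are
  then zeroed outside their level, so the copies occupy disjoint rows.

## Fitting

Penalized least squares on the assembled design (intercept, optional
factor dummy, smooth blocks): minimize ‖y − Xb‖² + Σ λⱼ b'Sⱼb, solved by
Cholesky on the penalized normal equations with a 1e-10·trace ridge
fallback. The Bayesian posterior covariance is φ(X'X + S_λ)⁻¹ and
φ = RSS/(n − edf), with edf the trace of the influence matrix (also
reported per term).

Smoothing parameters maximize the Gaussian restricted likelihood with φ
profiled out:

    -2 l_r = (n - M_p)(log(2π P/(n - M_p)) + 1) + log|X'X + S_λ| - log|S_λ|_+

where P is the penalized RSS and M_p the penalty null-space dimension.
Optimization is L-BFGS-B on log λ with numeric gradients, multi-started
from λ = 1e-3, 1, 1e3 for all penalties. GCV (γ = 1.4) is available as an
option; REML is the default.

**AR(1) errors.** Temporal dependence within a pixel is treated as a
working AR(1) correlation. The default "plug-in" estimator is the pooled
lag-1 autocorrelation of the ρ = 0 fit's residuals over within-pixel
consecutive pairs (pixels with < 3 epochs are skipped). Residuals are not
re-demeaned per pixel: the fit already centers them and per-pixel
demeaning biases the lag-1 estimate down by roughly (1 + 3ρ)/T. An
optional "search" mode refines ρ by golden-section search of the whitened
REML score (adding the (n − n_pixels)·log(1 − ρ²) log-determinant term),
refitting at each evaluation. Given ρ, rows are whitened — first row of
each pixel scaled by √(1 − ρ²), later rows r_t − ρ r_{t−1} — which makes
the transformed cross-products exactly (1 − ρ²) times the GLS ones, so
whitened OLS reproduces GLS coefficients; smoothing parameters are then
re-selected on the whitened data and the model refit.

## Inference outputs

"Summed effect" curves evaluate the full linear predictor over a grid of
one covariate with the others held at their training medians and the
factor at a chosen level; standard errors come from x'Vx with V the
posterior covariance. Prediction surfaces do the same on a lon/lat grid,
flag nodes outside the convex hull of the training pixels, and attach a
3×3 bivariate tercile classification (estimate terciles × SE terciles,
computed from the plotted sample itself, ties resolved to the lower
class) with a deterministic 9-color palette. Grid points outside the
training range of a covariate are linearly extrapolated with a warning.

Validation against an annual production series uses Shapiro–Wilk
normality checks on both series (scipy's standard approximation) and a
one-sided Pearson test for a positive correlation, computed in closed
form (r, df = n − 2, t = r√(df/(1 − r²)), upper-tail p); both the
intercept-inclusive and centered annual effect series are emitted (the
correlation is invariant to the shift).

Shipping activity is reduced to per-(port, month) means over raster cells
whose centers lie within a great-circle radius (default 20 km) of the
port, equally weighted, missing cells excluded; cumulative sums reset
each January, and the percent change from year a to b is
100·(cum_b[compare] − cum_a[compare})/cum_a[reference], both months
defaulting to the last month common to both years.

## Synthetic data and what passing tests show

`simulate_gpp` draws value = spatial(s) + seasonal(m) + trend(y) +
interaction + δ·1[date ≥ cutoff] + AR(1) noise + white noise. Defaults —
the package's study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| grid, epochs | 16×16 px, 2/month, 2020–2022 (18,432 rows) | minutes-scale fits with stable ρ and δ estimation |
| base level | 3.0 gC/m²/8d | cropland-scale GPP composite values |
| seasonal | amplitude 1.5, peak month 7 | pronounced temperate growing season; integer-month cosine sums to zero over a year |
| spatial field | two Gaussian bumps (+1.0, −0.8) on a 3°×3° extent | smooth regional contrast a k=50 GP can resolve |
| trend | 0 (opt-in) | the event model has no year term, so a trend would leak into the step; trend-bearing scenes are created explicitly where a trend is under test |
| step δ | −0.247 gC/m² at 2022-01-01 | detectable but not trivial at the default noise level |
| noise | AR(1) sd 0.3 with ρ 0.3, plus white sd 0.5 | realistic mix of persistent and independent observation error |

The cutoff sits at a calendar-year boundary rather than mid-season: with
by-level seasonal smooths, a mid-season cutoff makes a pure additive step
non-identifiable — the seasonal mean over the truncated post window can
trade off against the step along a penalty-resolved direction — so the
year-boundary design is the clean recovery experiment for an injected
step. Real records cut mid-season inherit that caveat: the step estimate
there is conditional on the penalty resolving the trade-off.

The generator emulates the statistical structure the model assumes and
deliberately omits features of real composites: no missing data or QA
artifacts, no skewed noise, no harvest-index decoupling between GPP and
production, no spatially correlated noise. Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
assumed structure, not performance on real satellite records.

`simulate_shipping` lays Gaussian-ridge corridors (equirectangular
point-to-segment distances) between ports with monthly lognormal
intensity noise, optionally zeroing all density within 60 km of named
ports during a blackout window; densities are clipped at zero.

## Numerical choices and edge cases

* Pixels are keyed by lon/lat rounded to 1e-6°; tables are sorted by
  (pixel, date) before whitening, and non-contiguous groups are rejected.
* The event cutoff is inclusive on the post side (the cutoff date itself
  is "post").
* Rows with missing values are dropped at ingest; CSV round-trips are
  bit-exact (17-significant-digit writes, round-trip float parsing).
* λ = 0 with a rank-deficient design raises an error naming (a superset
  of) the collinear columns via pivoted QR.
* Duplicate GP knots trigger one jitter-and-retry before erroring; fewer
  unique sites than k reduces k with a warning.
* The cubic-spline roughness penalty has a linear null space, so an
  infinite penalty leaves the best-fitting centered line for that term
  (edf → 1); cyclic, GP and tensor penalties are full rank after
  centering and collapse entirely.
* Replicate studies (step recovery, coverage) run on reduced scenes
  (10×10 and 6×6 pixel grids) with the tensor term dropped, since the
  generated truth contains no space×month interaction; the full
  tensor-bearing fit is exercised separately.
* Wald p-values use the t distribution with residual dof, switching to
  the normal approximation beyond dof 1e4; p-values are reported at
  machine precision, any "< 0.001" formatting is left to report layers.

## Known limitations

* One global ρ is shared by all pixels; heterogeneous temporal dependence
  is not modelled. When the true noise is AR(1)+white (an ARMA(1,1)),
  the plug-in targets the composite lag-1 correlation, which whitens the
  first lag but leaves a small tail.
* GeoTIFF I/O is not provided; rasters enter as ESRI ASCII grids, CSV, or
  in-memory arrays, assumed WGS84 (reprojection is the caller's job).
* A simple covariate-binning aid (`aggregate_binned`) rounds pixel
  coordinates and averages duplicate rows into frequency weights, which
  the fit honours by sqrt-weight row scaling with n replaced by the
  weight sum. It is off by default and not bit-exact with the unbinned
  fit; beyond it, fits are dense and intended for up to ~10⁵ rows.
* Tercile classes are computed from the plotted sample, so classes are
  not comparable across maps with different samples.
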