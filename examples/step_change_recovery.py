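"""Fit the pre/post event model to a synthetic scene with a known step.

Generates the default synthetic scene — a 16x16 pixel grid observed twice a
month for 2020-2022 with a -0.247 gC/m^2 step injected at 2022-01-01 —
fits the event-factor model (month and spatial smooths per period, AR(1)
whitening), and prints the Wald test of the step coefficient.
"""

from geoseason import ModelConfig, SimConfig, event_effect_test, fit_eq2, simulate_gpp

table, truth = simulate_gpp(SimConfig(seed=1))
print(f"scene: {len(table)} observations, injected step {truth.delta} gC/m^2")

fit = fit_eq2(table, ModelConfig(space_k=25, include_tensors=False))
est, se, t, p = event_effect_test(fit)
print(f"estimated step : {est:.4f} gC/m^2 (SE {se:.4f})")
print(f"Wald test      : t = {t:.2f}, p = {p:.2e}")
# The scene's noise is AR(1) (sd 0.3, rho 0.3) plus white noise (sd 0.5);
# the residual lag-1 correlation of that mixture is rho*0.3^2/(0.3^2+0.5^2)
# ~ 0.08, which is what the plug-in estimate targets.
print(f"AR(1) rho      : {fit.rho:.3f} (residual lag-1 of the mixed noise ~ 0.08)")
print(f"effective dof  : {fit.edf_total:.1f} of {len(fit.beta)} coefficients")
# The step estimate should sit within ~2 SE of the injected truth; the
# negative t at tiny p mirrors how a post-event productivity drop surfaces.
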