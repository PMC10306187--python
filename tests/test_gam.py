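import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from geoseason.basis import SmoothSpec
from geoseason.gam import (
    ARSpec,
    ModelConfig,
    assemble_design,
    estimate_rho,
    fit_eq2,
    fit_penalized,
    select_lambda_reml,
    whiten_ar1,
)
from geoseason.simulate import SimConfig, simulate_gpp

from conftest import random_long_table


def _eq1_specs():
    return [
        SmoothSpec("crs", ("year",), k=6),
        SmoothSpec("cyclic", ("month",), k=12, period=12.0),
        SmoothSpec("gp", ("longitude", "latitude"), k=15),
    ]


class TestAssemble:
    def test_column_count_intercept_plus_blocks(self):
        tab = random_long_table(800, seed=1)
        d = assemble_design(tab, _eq1_specs(), ModelConfig())
        expected = 1 + sum(t.block.p for t in d.terms)
        assert d.X.shape[1] == expected
        assert d.col_labels[0] == "(Intercept)"

    def test_event_factor_adds_column_and_doubles_by_blocks(self):
        tab = random_long_table(800, seed=1)
        specs = [SmoothSpec("cyclic", ("month",), k=12, period=12.0, by="war")]
        d = assemble_design(tab, specs, ModelConfig(), event_factor=True)
        assert d.col_labels[1] == "war[post]"
        assert len(d.terms) == 2  # pre and post copies
        assert {t.level for t in d.terms} == {"pre", "post"}

    def test_deterministic_rebuild(self):
        tab = random_long_table(400, seed=2)
        d1 = assemble_design(tab, _eq1_specs(), ModelConfig())
        d2 = assemble_design(tab, _eq1_specs(), ModelConfig())
        np.testing.assert_array_equal(d1.X, d2.X)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_design(random_long_table(0), _eq1_specs(), ModelConfig())


class TestPenalizedFit:
    def test_lambda_zero_matches_direct_least_squares(self):
        tab = random_long_table(600, seed=3)
        d = assemble_design(tab, _eq1_specs(), ModelConfig())
        fit = fit_penalized(d, np.zeros(len(d.penalties)))
        beta_ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)

    def test_infinite_penalty_collapses_full_rank_smooths(self):
        # cyclic and gp penalties are full rank after centering, so the
        # fit collapses to the intercept-only model
        tab = random_long_table(600, seed=4)
        specs = [
            SmoothSpec("cyclic", ("month",), k=12, period=12.0),
            SmoothSpec("gp", ("longitude", "latitude"), k=15),
        ]
        d = assemble_design(tab, specs, ModelConfig())
        fit = fit_penalized(d, np.full(len(d.penalties), 1e12))
        assert abs(fit.beta[0] - d.y.mean()) < 1e-6
        assert np.abs(d.X[:, 1:] @ fit.beta[1:]).max() < 1e-4
        assert fit.edf_total == pytest.approx(1.0, abs=0.01)

    def test_single_smooth_recovers_known_cubic(self):
        rs = np.random.default_rng(5)
        x = rs.uniform(0, 1, 500)
        f_true = lambda x: 2 * x**3 - 3 * x**2 + x
        tab = random_long_table(500, seed=5)
        tab["year"] = 2010 + np.round(12 * x).astype(int)  # 13 distinct levels
        xg = (tab["year"] - 2010) / 12.0
        tab["gpp"] = f_true(xg) + rs.normal(0, 0.01, 500)
        d = assemble_design(tab, [SmoothSpec("crs", ("year",), k=13)], ModelConfig())
        lam = select_lambda_reml(d)
        fit = fit_penalized(d, lam)
        from geoseason.gam import _sorted_table

        sorted_tab, _ = _sorted_table(tab)
        xs = (sorted_tab["year"].to_numpy() - 2010) / 12.0
        truth = f_true(xs) - f_true(xs).mean() + sorted_tab["gpp"].mean()
        rmse = np.sqrt(np.mean((d.X @ fit.beta - truth) ** 2))
        assert rmse < 0.05

    def test_hat_trace_equals_summed_edf(self):
        tab = random_long_table(400, seed=6)
        d = assemble_design(tab, _eq1_specs(), ModelConfig())
        fit = fit_penalized(d, np.ones(len(d.penalties)))
        A = d.X.T @ d.X + sum(
            lam * _embed(S, sl, d.X.shape[1]) for lam, (sl, S, _) in zip(fit.lambdas, d.penalties)
        )
        H = d.X @ np.linalg.solve(A, d.X.T)
        assert np.trace(H) == pytest.approx(fit.edf_total, abs=1e-6)
        assert np.trace(H) == pytest.approx(sum(fit.edf_by_term.values()), abs=1e-6)

    def test_negative_lambda_rejected(self):
        tab = random_long_table(100, seed=7)
        d = assemble_design(tab, [SmoothSpec("crs", ("year",), k=5)], ModelConfig())
        with pytest.raises(ValueError):
            fit_penalized(d, [-1.0])


def _embed(S, sl, p):
    out = np.zeros((p, p))
    out[sl, sl] = S
    return out


class TestREML:
    def test_pure_noise_shrinks_every_smooth(self):
        tab = random_long_table(3000, seed=8)
        d = assemble_design(tab, _eq1_specs(), ModelConfig())
        lam = select_lambda_reml(d)
        fit = fit_penalized(d, lam)
        # cubic year smooth keeps its linear null space (edf ~ 1); the
        # wiggle and the full-rank smooths must shrink away
        assert fit.edf_by_term["s(year)"] < 1.5
        assert fit.edf_by_term["s(month,cc)"] < 1.5
        assert fit.edf_by_term["s(lon,lat)"] < 1.5

    def test_strong_signal_matches_grid_search_oracle(self):
        rs = np.random.default_rng(9)
        tab = random_long_table(800, seed=9)
        m = tab["month"].to_numpy(dtype=float)
        tab["gpp"] = np.sin(2 * np.pi * m / 12) + rs.normal(0, 0.1, 800)
        d = assemble_design(tab, [SmoothSpec("cyclic", ("month",), k=12, period=12.0)], ModelConfig())
        lam = select_lambda_reml(d)
        edf_opt = fit_penalized(d, lam).edf_total
        # brute-force grid over log-lambda
        from geoseason.gam import _penalty_groups, _reml_score

        XtX, Xty, yty = d.X.T @ d.X, d.X.T @ d.y, float(d.y @ d.y)
        groups = _penalty_groups(d)
        mp = d.X.shape[1] - sum(r for _, _, r in groups)
        grid = np.linspace(-12, 12, 97)
        scores = [_reml_score(d, XtX, Xty, yty, groups, mp, np.array([g])) for g in grid]
        lam_grid = np.exp(grid[int(np.argmin(scores))])
        edf_grid = fit_penalized(d, [lam_grid]).edf_total
        assert abs(edf_opt - edf_grid) < 1.0

    def test_lambda_invariant_to_response_rescaling(self):
        tab = random_long_table(600, seed=10)
        d1 = assemble_design(tab, [SmoothSpec("cyclic", ("month",), k=12, period=12.0)], ModelConfig())
        lam1 = select_lambda_reml(d1)
        tab2 = tab.copy()
        tab2["gpp"] = tab2["gpp"] * 7.0
        d2 = assemble_design(tab2, [SmoothSpec("cyclic", ("month",), k=12, period=12.0)], ModelConfig())
        lam2 = select_lambda_reml(d2)
        # Gaussian REML: lambda is scale free (phi absorbs the rescaling)
        assert np.allclose(np.log(lam1), np.log(lam2), atol=0.2)


class TestRho:
    def _fit0(self, cfg):
        tab, _ = simulate_gpp(cfg)
        d = assemble_design(tab, [], ModelConfig())
        return fit_penalized(d, [])

    def test_white_noise_gives_near_zero_rho(self):
        cfg = SimConfig(nx=20, ny=10, years=(2021, 2022), epochs_per_month=2, sigma=0.5,
                        ar_sd=0.0, delta=0.0, seasonal_amplitude=0.0, bumps=(), seed=11)
        assert abs(estimate_rho(self._fit0(cfg))) < 0.05

    def test_ar1_rho_recovered(self):
        cfg = SimConfig(nx=20, ny=10, years=(2021, 2022), epochs_per_month=2, sigma=0.0,
                        ar_sd=0.5, rho=0.6, delta=0.0, seasonal_amplitude=0.0, bumps=(), seed=12)
        assert 0.55 < estimate_rho(self._fit0(cfg)) < 0.65

    def test_constant_residuals_error(self):
        cfg = SimConfig(nx=5, ny=5, years=(2021, 2021), sigma=0.0, ar_sd=0.0,
                        delta=0.0, seasonal_amplitude=0.0, bumps=(), seed=13)
        tab, _ = simulate_gpp(cfg)
        d = assemble_design(tab, [], ModelConfig())
        fit = fit_penalized(d, [])
        with pytest.raises(ValueError, match="constant|degenerate"):
            estimate_rho(fit)


class TestWhiten:
    def _design(self, n_groups=5, T=30, seed=14, with_smooth=True):
        rs = np.random.default_rng(seed)
        n = n_groups * T
        tab = pd.DataFrame(
            {
                "longitude": np.repeat(np.arange(n_groups) + 30.0, T),
                "latitude": np.repeat(np.arange(n_groups) + 46.0, T),
                "date": np.tile(pd.date_range("2012-01-01", periods=T, freq="90D"), n_groups),
                "gpp": rs.normal(size=n),
            }
        )
        from geoseason.data_model import add_calendar_columns, label_event

        tab = label_event(add_calendar_columns(tab))
        specs = [SmoothSpec("crs", ("year",), k=4)] if with_smooth else []
        return assemble_design(tab, specs, ModelConfig())

    def test_rho_zero_is_identity(self):
        d = self._design()
        dw = whiten_ar1(d, ARSpec(0.0, d.group))
        np.testing.assert_array_equal(dw.X, d.X)
        np.testing.assert_array_equal(dw.y, d.y)

    def test_whitening_removes_lag1_autocorrelation(self):
        rho = 0.6
        rs = np.random.default_rng(15)
        d = self._design(n_groups=50, T=60, seed=15)
        # overwrite response with pure AR(1) noise per group
        y = np.empty(len(d.y))
        for g in np.unique(d.group):
            idx = np.where(d.group == g)[0]
            e = rs.normal(0, 1, len(idx))
            z = np.empty(len(idx))
            z[0] = e[0]
            for t in range(1, len(idx)):
                z[t] = rho * z[t - 1] + np.sqrt(1 - rho**2) * e[t]
            y[idx] = z
        d.y = y
        dw = whiten_ar1(d, ARSpec(rho, d.group))
        r = dw.y
        acs = []
        for g in np.unique(d.group):
            rg = r[d.group == g]
            rg = rg - rg.mean()
            acs.append((rg[1:] @ rg[:-1]) / (rg @ rg))
        assert abs(np.mean(acs)) < 0.05

    def test_whitened_ols_equals_brute_force_gls(self):
        rho = 0.6
        d = self._design(n_groups=4, T=25, seed=16)  # n = 100 <= 200
        n = len(d.y)
        dw = whiten_ar1(d, ARSpec(rho, d.group))
        fit = fit_penalized(dw, [0.7])
        # explicit AR(1) covariance oracle
        Sig = np.zeros((n, n))
        for g in np.unique(d.group):
            idx = np.where(d.group == g)[0]
            lag = np.abs(np.subtract.outer(np.arange(len(idx)), np.arange(len(idx))))
            Sig[np.ix_(idx, idx)] = rho**lag
        Si = np.linalg.inv(Sig)
        p = d.X.shape[1]
        S = np.zeros((p, p))
        sl, Sj, _ = d.penalties[0]
        S[sl, sl] = 0.7 * Sj
        # whitening scales X'Sigma^{-1}X by (1-rho^2)
        bg = np.linalg.solve((1 - rho**2) * (d.X.T @ Si @ d.X) + S, (1 - rho**2) * (d.X.T @ Si @ d.y))
        np.testing.assert_allclose(fit.beta, bg, atol=1e-10)

    def test_single_observation_groups_only_scaled(self):
        d = self._design(n_groups=5, T=1, with_smooth=False)
        dw = whiten_ar1(d, ARSpec(0.6, d.group))
        np.testing.assert_allclose(dw.y, np.sqrt(1 - 0.36) * d.y)

    def test_unsorted_groups_rejected(self):
        d = self._design()
        bad = d.group.copy()
        bad[::2] = bad[::-2]
        with pytest.raises(ValueError, match="contiguous"):
            whiten_ar1(d, ARSpec(0.5, bad))


class TestModelFits:
    def test_null_scene_war_coefficient_near_zero(self, fast_config):
        hits = 0
        reps = 8
        for i in range(reps):
            cfg = SimConfig(nx=6, ny=6, delta=0.0, seasonal_amplitude=0.0,
                            trend_slope=0.0, bumps=(), seed=200 + i)
            tab, _ = simulate_gpp(cfg)
            fit = fit_eq2(tab, fast_config)
            if abs(fit.war_coefficient) <= 2 * fit.war_se:
                hits += 1
        assert hits >= int(0.75 * reps)

    def test_deterministic_replay(self, fast_config):
        cfg = SimConfig(nx=6, ny=6, seed=300)
        t1, _ = simulate_gpp(cfg)
        t2, _ = simulate_gpp(cfg)
        f1 = fit_eq2(t1, fast_config)
        f2 = fit_eq2(t2, fast_config)
        np.testing.assert_array_equal(f1.beta, f2.beta)

    def test_full_model_with_tensor_terms_runs_and_recovers_step(self):
        cfg = SimConfig(nx=6, ny=6, seed=320)
        tab, truth = simulate_gpp(cfg)
        fit = fit_eq2(tab, ModelConfig(space_k=15, tensor_space_k=8))
        assert abs(fit.war_coefficient - truth.delta) <= 3 * fit.war_se
        # tensor copies present in the design
        assert any("te(" in t.label for t in fit.design.terms)

    def test_binned_fit_close_to_unbinned(self):
        from geoseason.data_model import aggregate_binned

        cfg = SimConfig(nx=12, ny=12, seed=330)
        tab, _ = simulate_gpp(cfg)
        config = ModelConfig(space_k=20, include_tensors=False)
        full = fit_eq2(tab, config)
        binned = fit_eq2(aggregate_binned(tab, 0, 0), config)
        assert len(binned.design.y) < len(full.design.y)
        assert abs(binned.war_coefficient - full.war_coefficient) < 0.5 * full.war_se

    def test_war_coefficient_matches_mgcv_reference(self):
        """Independent oracle: mgcv's REML fit of the same event model."""
        cfg = SimConfig(nx=8, ny=8, seed=7)
        tab, _ = simulate_gpp(cfg)
        fit = fit_eq2(tab, ModelConfig(space_k=20, include_tensors=False, rho_mode="none"))
        script = textwrap.dedent(
            """
            suppressMessages(library(mgcv))
            d <- read.csv('{csv}')
            d$war <- factor(d$war, levels=c('pre','post'))
            m <- gam(gpp ~ war + s(month, bs='cc', k=12, by=war)
                     + s(longitude, latitude, bs='gp', k=20, by=war),
                     data=d, method='REML')
            s <- summary(m)
            cat(s$p.coeff['warpost'], s$se['warpost'], sep='\\n')
            """
        )
        import tempfile, os

        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "sim.csv")
            tab[["longitude", "latitude", "gpp", "month", "war"]].to_csv(csv, index=False)
            try:
                out = subprocess.run(
                    ["Rscript", "-e", script.format(csv=csv)],
                    capture_output=True, text=True, timeout=300, check=True,
                )
            except (FileNotFoundError, subprocess.CalledProcessError) as exc:
                pytest.skip(f"mgcv oracle unavailable: {exc}")
        ref_est, ref_se = map(float, out.stdout.split())
        assert fit.war_coefficient == pytest.approx(ref_est, abs=1e-3)
        assert fit.war_se == pytest.approx(ref_se, rel=0.05)
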