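"""Penalized additive-model fitting with REML and AR(1) errors.

The model for an observation z_i at pixel s_i, month m_i, year y_i is

    z_i ~ N(mu_i, phi),
    mu_i = beta + f1(y_i) + f2(m_i) + f3(s_i) + f4(y_i, m_i) + f5(s_i, y_i)

(the trend model), or, for the pre/post event comparison,

    mu_i = beta + w_i + f1(m_i) w_i + f2(s_i) w_i + f3(s_i, m_i) w_i

where w_i is a two-level factor (treatment coded, "pre" as reference) and
the f w products are factor-"by" smooth copies, one per level.  Smooths are
penalized regression splines; smoothing parameters are chosen by Gaussian
restricted maximum likelihood (REML; GCV available as an option).  Residual
temporal dependence within a pixel is handled by an AR(1) working
correlation: the lag-1 correlation rho is estimated from the residuals of
the rho=0 fit (plug-in, with an optional golden-section refinement), the
data are whitened by the AR(1) Cholesky transform, and the model is refit,
so generalized least squares reduces to ordinary least squares on the
transformed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from . import basis as _basis
from .basis import BasisBlock, SmoothSpec, apply_sum_to_zero

__all__ = [
    "ARSpec",
    "ModelConfig",
    "FittedGAM",
    "DesignMatrices",
    "assemble_design",
    "fit_penalized",
    "select_lambda_reml",
    "estimate_rho",
    "whiten_ar1",
    "fit_eq1",
    "fit_eq2",
    "eq1_specs",
    "eq2_specs",
]

DEFAULT_SEED = 20230628


# ---------------------------------------------------------------------------
# configuration and containers


@dataclass
class ARSpec:
    """First-order autoregressive working-correlation specification."""

    rho: float
    group: np.ndarray  # integer pixel id per row; contiguous, date-ordered

    def __post_init__(self):
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")


@dataclass
class ModelConfig:
    """Tunable knobs of the two model fits.

    ``year_k`` defaults to the number of unique years; ``space_k`` is the
    spatial GP basis dimension (capped at the number of unique pixels);
    ``tensor_space_k`` is the (smaller) spatial rank used inside tensor
    interactions.  ``rho_mode`` is "plugin", "search", "none", or a fixed
    float.
    """

    year_k: int | None = None
    month_k: int = 12
    space_k: int = 50
    tensor_space_k: int = 20
    include_tensors: bool = True
    gp_range: float | None = None
    distance_mode: str = "km"
    criterion: str = "reml"  # or "gcv"
    rho_mode: object = "plugin"
    seed: int = DEFAULT_SEED


@dataclass
class TermInfo:
    label: str
    sl: slice
    block: BasisBlock
    covariates: tuple
    level: str | None = None  # by-factor level, if any


@dataclass
class DesignMatrices:
    X: np.ndarray
    y: np.ndarray
    terms: list
    penalties: list  # (slice, matrix, label) triples
    col_labels: list
    group: np.ndarray
    has_factor: bool
    table_refs: dict  # reference covariate values for prediction
    n_eff: float | None = None  # sum of frequency weights, if weighted

    @property
    def nobs(self) -> float:
        return self.n_eff if self.n_eff is not None else len(self.y)


@dataclass
class FittedGAM:
    """Coefficients, posterior covariance and metadata of one fit."""

    beta: np.ndarray
    cov: np.ndarray
    phi: float
    lambdas: np.ndarray
    rho: float
    edf_total: float
    edf_by_term: dict
    design: DesignMatrices
    n: int
    rss: float
    criterion_value: float
    config: ModelConfig | None = None

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def has_factor(self) -> bool:
        return self.design.has_factor

    @property
    def war_coefficient(self) -> float:
        if not self.has_factor:
            raise ValueError("fit has no event factor")
        return float(self.beta[1])

    @property
    def war_se(self) -> float:
        if not self.has_factor:
            raise ValueError("fit has no event factor")
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def residual_df(self) -> float:
        return self.n - self.edf_total

    def predict_rows(self, newdata: pd.DataFrame) -> np.ndarray:
        """Model-matrix rows for new covariate values (same column order)."""
        n = len(newdata)
        X = np.zeros((n, len(self.beta)))
        X[:, 0] = 1.0
        if self.has_factor:
            X[:, 1] = (newdata["war"].to_numpy() == "post").astype(float)
        for t in self.design.terms:
            vals = [newdata[c].to_numpy() for c in t.covariates]
            M = t.block.evaluate(*vals)
            if t.level is not None:
                ind = (newdata["war"].to_numpy() == t.level).astype(float)
                M = M * ind[:, None]
            X[:, t.sl] = M
        return X

    def predict(self, newdata: pd.DataFrame, se: bool = False):
        X = self.predict_rows(newdata)
        est = X @ self.beta
        if not se:
            return est
        sev = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return est, sev


# ---------------------------------------------------------------------------
# design assembly


def _sorted_table(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sort by (pixel, date); return table and integer pixel ids."""
    from .data_model import pixel_key

    key = pixel_key(table)
    order = np.lexsort((pd.to_datetime(table["date"]).to_numpy(), key.to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    codes, _ = pd.factorize(pixel_key(table), sort=False)
    return table, codes


def _build_block(spec: SmoothSpec, table: pd.DataFrame, config: ModelConfig) -> BasisBlock:
    if spec.kind == "crs":
        (cov,) = spec.covariates
        x = table[cov].to_numpy(dtype=float)
        k = spec.k
        block = _basis.crs_basis(x, k=k, label=f"s({cov})")
    elif spec.kind == "cyclic":
        (cov,) = spec.covariates
        x = table[cov].to_numpy(dtype=float)
        block = _basis.cyclic_basis(
            x, k=spec.k, period=spec.period, lower=1.0, label=f"s({cov},cc)"
        )
    elif spec.kind == "gp":
        lon = table[spec.covariates[0]].to_numpy(dtype=float)
        lat = table[spec.covariates[1]].to_numpy(dtype=float)
        block = _basis.gp_basis(
            np.column_stack([lon, lat]),
            k=spec.k,
            rng=spec.gp_range,
            distance_mode=spec.distance_mode,
            label="s(lon,lat)",
        )
    elif spec.kind == "tensor":
        margins = [
            apply_sum_to_zero(_build_block(m, table, config)) for m in spec.marginals
        ]
        block = margins[0]
        for m in margins[1:]:
            block = _basis.tensor_interaction(block, m)
        return block  # marginals already constrained; tensor excludes main effects
    else:  # pragma: no cover
        raise ValueError(f"unknown smooth kind {spec.kind!r}")
    return apply_sum_to_zero(block)


def eq1_specs(table: pd.DataFrame, config: ModelConfig) -> list[SmoothSpec]:
    """Smooth terms of the trend model: year, month, space, and tensors."""
    n_years = table["year"].nunique()
    year_k = config.year_k or n_years
    space_k = min(config.space_k, _n_pixels(table))
    specs = [
        SmoothSpec("crs", ("year",), k=year_k),
        SmoothSpec("cyclic", ("month",), k=config.month_k, period=12.0),
        SmoothSpec(
            "gp", ("longitude", "latitude"), k=space_k,
            gp_range=config.gp_range, distance_mode=config.distance_mode,
        ),
    ]
    if config.include_tensors:
        tk = min(config.tensor_space_k, _n_pixels(table))
        specs += [
            SmoothSpec(
                "tensor", ("year", "month"),
                marginals=(
                    SmoothSpec("crs", ("year",), k=year_k),
                    SmoothSpec("cyclic", ("month",), k=config.month_k, period=12.0),
                ),
            ),
            SmoothSpec(
                "tensor", ("longitude", "latitude", "year"),
                marginals=(
                    SmoothSpec(
                        "gp", ("longitude", "latitude"), k=tk,
                        gp_range=config.gp_range, distance_mode=config.distance_mode,
                    ),
                    SmoothSpec("crs", ("year",), k=year_k),
                ),
            ),
        ]
    return specs


def eq2_specs(table: pd.DataFrame, config: ModelConfig) -> list[SmoothSpec]:
    """Smooth terms of the event model: month, space (and tensor), by war."""
    space_k = min(config.space_k, _n_pixels(table))
    specs = [
        SmoothSpec("cyclic", ("month",), k=config.month_k, period=12.0, by="war"),
        SmoothSpec(
            "gp", ("longitude", "latitude"), k=space_k, by="war",
            gp_range=config.gp_range, distance_mode=config.distance_mode,
        ),
    ]
    if config.include_tensors:
        tk = min(config.tensor_space_k, _n_pixels(table))
        specs.append(
            SmoothSpec(
                "tensor", ("longitude", "latitude", "month"), by="war",
                marginals=(
                    SmoothSpec(
                        "gp", ("longitude", "latitude"), k=tk,
                        gp_range=config.gp_range, distance_mode=config.distance_mode,
                    ),
                    SmoothSpec("cyclic", ("month",), k=config.month_k, period=12.0),
                ),
            )
        )
    return specs


def _n_pixels(table: pd.DataFrame) -> int:
    from .data_model import pixel_key

    return int(pixel_key(table).nunique())


def assemble_design(
    table: pd.DataFrame,
    specs: list[SmoothSpec],
    config: ModelConfig | None = None,
    event_factor: bool = False,
    response: str = "gpp",
) -> DesignMatrices:
    """Build the full model matrix, penalties and response vector.

    Column order: intercept, event-factor dummy (if present), then smooth
    blocks in spec order (by-factor smooths contribute one copy per level,
    pre before post).  The table is sorted by (pixel, date) so AR(1)
    whitening can run on contiguous groups.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    config = config or ModelConfig()
    table, group = _sorted_table(table)
    y = table[response].to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones((len(table), 1))]
    col_labels = ["(Intercept)"]
    if event_factor:
        post = (table["war"].to_numpy() == "post").astype(float)
        cols.append(post[:, None])
        col_labels.append("war[post]")
    terms: list[TermInfo] = []
    penalties: list[tuple] = []
    start = sum(c.shape[1] for c in cols)
    for spec in specs:
        block = _build_block(spec, table, config)
        if spec.by is not None:
            ind = table[spec.by].to_numpy()
            for level in ("pre", "post"):
                lev_ind = (ind == level).astype(float)
                bl = _basis.by_factor(block, lev_ind, label=f"{block.label}:{level}")
                sl = slice(start, start + bl.p)
                terms.append(TermInfo(bl.label, sl, bl, spec.covariates, level))
                for S in bl.penalties:
                    penalties.append((sl, S, bl.label))
                cols.append(bl.X)
                col_labels += [f"{bl.label}.{j}" for j in range(bl.p)]
                start += bl.p
        else:
            sl = slice(start, start + block.p)
            terms.append(TermInfo(block.label, sl, block, spec.covariates))
            for S in block.penalties:
                penalties.append((sl, S, block.label))
            cols.append(block.X)
            col_labels += [f"{block.label}.{j}" for j in range(block.p)]
            start += block.p

    X = np.hstack(cols)
    refs = {
        c: float(table[c].median())
        for c in ("year", "month", "longitude", "latitude")
        if c in table.columns
    }
    n_eff = None
    if "weight" in table.columns:  # frequency weights from covariate binning
        w = table["weight"].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        sw = np.sqrt(w)
        X = X * sw[:, None]
        y = y * sw
        n_eff = float(w.sum())
    return DesignMatrices(
        X=X, y=y, terms=terms, penalties=penalties, col_labels=col_labels,
        group=group, has_factor=event_factor, table_refs=refs, n_eff=n_eff,
    )


# ---------------------------------------------------------------------------
# penalized least squares


def _penalty_total(design: DesignMatrices, lambdas) -> np.ndarray:
    p = design.X.shape[1]
    S = np.zeros((p, p))
    for lam, (sl, Sj, _) in zip(lambdas, design.penalties):
        S[sl, sl] += lam * Sj
    return S


def _solve(A: np.ndarray):
    """Cholesky solve with a small ridge fallback on singularity."""
    try:
        return cho_factor(A), 0.0
    except np.linalg.LinAlgError:
        pass
    ridge = 1e-10 * np.trace(A) / A.shape[0]
    for _ in range(3):
        try:
            return cho_factor(A + ridge * np.eye(A.shape[0])), ridge
        except np.linalg.LinAlgError:
            ridge *= 100
    raise np.linalg.LinAlgError("normal equations remain singular after ridge fallback")


def fit_penalized(design: DesignMatrices, lambdas, rho: float = 0.0,
                  config: ModelConfig | None = None) -> FittedGAM:
    """Penalized least-squares fit at fixed smoothing parameters.

    Minimizes ||y - X b||^2 + sum_j lambda_j b' S_j b.  The posterior
    (Bayesian) covariance is phi (X'X + S_lambda)^{-1} and the scale is
    phi = RSS / (n - edf).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) != len(design.penalties):
        raise ValueError("one lambda per penalty required")
    if np.any(lambdas < 0):
        raise ValueError("lambdas must be >= 0")
    X, y = design.X, design.y
    n, p = design.nobs, X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    A = XtX + _penalty_total(design, lambdas)
    if np.all(lambdas == 0):
        rank = np.linalg.matrix_rank(XtX)
        if rank < p:
            # name (a superset of) the collinear columns via pivoted QR
            from scipy.linalg import qr as _qr

            _, _, piv = _qr(X, mode="economic", pivoting=True)
            bad = [design.col_labels[j] for j in piv[rank:]]
            raise np.linalg.LinAlgError(
                f"design is rank deficient with all lambda=0; collinear columns: {bad}"
            )
    cA, _ = _solve(A)
    beta = cho_solve(cA, Xty)
    resid = y - X @ beta
    rss = float(resid @ resid)
    Ainv_XtX = cho_solve(cA, XtX)
    edf_i = np.diag(Ainv_XtX)
    edf_total = float(edf_i.sum())
    phi = rss / max(n - edf_total, 1.0)
    Ainv = cho_solve(cA, np.eye(p))
    cov = phi * 0.5 * (Ainv + Ainv.T)
    edf_by_term = {"parametric": float(edf_i[: design.terms[0].sl.start].sum()) if design.terms else edf_total}
    for t in design.terms:
        edf_by_term[t.label] = float(edf_i[t.sl].sum())
    return FittedGAM(
        beta=beta, cov=cov, phi=phi, lambdas=lambdas, rho=rho,
        edf_total=edf_total, edf_by_term=edf_by_term, design=design,
        n=n, rss=rss, criterion_value=np.nan, config=config,
    )


# ---------------------------------------------------------------------------
# smoothing-parameter selection


def _penalty_groups(design: DesignMatrices):
    """Group penalties sharing a coefficient block (tensor margins)."""
    groups: dict = {}
    for j, (sl, S, label) in enumerate(design.penalties):
        key = (sl.start, sl.stop)
        groups.setdefault(key, []).append(j)
    out = []
    for (a, b), idx in groups.items():
        Ssum = sum(design.penalties[j][1] for j in idx)
        rank = int(np.linalg.matrix_rank(Ssum, hermitian=True))
        out.append((slice(a, b), idx, rank))
    return out


def _reml_score(design: DesignMatrices, XtX, Xty, yty, groups, mp, log_lambdas) -> float:
    """-2 x restricted log-likelihood with phi profiled out."""
    lambdas = np.exp(log_lambdas)
    n = design.nobs
    A = XtX + _penalty_total(design, lambdas)
    try:
        cA, ridge = _solve(A)
    except np.linalg.LinAlgError:
        return np.inf
    beta = cho_solve(cA, Xty)
    rss = max(yty - 2 * beta @ Xty + beta @ (XtX @ beta), 1e-300)
    pen = 0.0
    logdet_S = 0.0
    for sl, idx, rank in groups:
        Sg = sum(lambdas[j] * design.penalties[j][1] for j in idx)
        pen += beta[sl] @ Sg @ beta[sl]
        w = np.linalg.eigvalsh(Sg)
        w = np.sort(w)[::-1][:rank]
        logdet_S += float(np.sum(np.log(np.maximum(w, 1e-300))))
    P = rss + max(pen, 0.0)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(cA[0]))))
    nmp = n - mp
    return nmp * (np.log(2 * np.pi * P / nmp) + 1.0) + logdet_A - logdet_S


def _gcv_score(design: DesignMatrices, XtX, Xty, yty, log_lambdas, gamma=1.4) -> float:
    lambdas = np.exp(log_lambdas)
    n = design.nobs
    A = XtX + _penalty_total(design, lambdas)
    try:
        cA, _ = _solve(A)
    except np.linalg.LinAlgError:
        return np.inf
    beta = cho_solve(cA, Xty)
    rss = max(yty - 2 * beta @ Xty + beta @ (XtX @ beta), 1e-300)
    edf = float(np.trace(cho_solve(cA, XtX)))
    denom = max(n - gamma * edf, 1e-8)
    return n * rss / denom**2


def select_lambda_reml(
    design: DesignMatrices,
    criterion: str = "reml",
    starts=(1e-3, 1.0, 1e3),
    maxiter: int = 200,
) -> np.ndarray:
    """Choose smoothing parameters by minimizing the REML (or GCV) score.

    Quasi-Newton (L-BFGS-B) on log-lambda with numeric gradients,
    multi-started from each value in *starts* applied to all penalties.
    """
    nlam = len(design.penalties)
    if nlam == 0:
        raise ValueError("no penalties to select")
    X, y = design.X, design.y
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    groups = _penalty_groups(design)
    p_pen = sum(sl.stop - sl.start for sl, _, _ in groups)
    rank_total = sum(r for _, _, r in groups)
    mp = X.shape[1] - rank_total  # penalty null-space dim incl. parametric cols
    if criterion == "reml":
        fun = lambda ll: _reml_score(design, XtX, Xty, yty, groups, mp, ll)
    elif criterion == "gcv":
        fun = lambda ll: _gcv_score(design, XtX, Xty, yty, ll)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = None
    for s in starts:
        x0 = np.full(nlam, np.log(s))
        res = minimize(
            fun, x0, method="L-BFGS-B",
            bounds=[(-16.0, 18.0)] * nlam,
            options={"maxiter": maxiter, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and best.fun == np.inf:
        warnings.warn("smoothing-parameter optimization failed to converge")
    return np.exp(best.x)


# ---------------------------------------------------------------------------
# AR(1) machinery


def estimate_rho(fit0: FittedGAM, mode: object = "plugin") -> float:
    """Estimate the within-pixel lag-1 residual autocorrelation.

    Default ("plugin"): pooled lag-1 autocorrelation of the rho=0 fit's
    residuals over within-pixel consecutive pairs (the model itself centers
    the residuals; per-pixel demeaning is avoided since it biases the
    estimate down by about (1+3 rho)/T).  "search" refines the plug-in
    value by golden-section search of the whitened REML score over rho in
    (0, 0.99), refitting at each evaluation.  Pixels with fewer than 3
    epochs are skipped.
    """
    if isinstance(mode, (int, float)):
        return float(mode)
    design = fit0.design
    resid = design.y - design.X @ fit0.beta
    group = design.group
    num = 0.0
    den = 0.0
    used = 0
    for g in np.unique(group):
        r = resid[group == g]
        if len(r) < 3:
            continue
        num += float(r[1:] @ r[:-1])
        den += float(r @ r)
        used += 1
    if used == 0:
        raise ValueError("no pixel has >= 3 epochs; cannot estimate rho")
    if den <= 1e-20 * max(1.0, float(design.y @ design.y)):
        raise ValueError("degenerate (constant) residuals; autocorrelation undefined")
    rho = num / den
    rho = float(np.clip(rho, -0.98, 0.98))
    if mode == "plugin":
        return rho
    if mode == "search":

        def score(r):
            d = whiten_ar1(design, ARSpec(r, design.group))
            lam = select_lambda_reml(d)
            XtX, Xty, yty = d.X.T @ d.X, d.X.T @ d.y, float(d.y @ d.y)
            groups = _penalty_groups(d)
            mp = d.X.shape[1] - sum(rk for _, _, rk in groups)
            # whitening changes |Sigma|: add its log-determinant term
            n_first = len(np.unique(d.group))
            ldet_sigma = (len(d.y) - n_first) * np.log(1 - r**2)
            return _reml_score(d, XtX, Xty, yty, groups, mp, np.log(lam)) + ldet_sigma

        res = minimize_scalar(score, bounds=(0.0, 0.99), method="bounded",
                              options={"xatol": 5e-3})
        return float(res.x)
    raise ValueError(f"unknown rho mode {mode!r}")


def whiten_ar1(design: DesignMatrices, ar: ARSpec) -> DesignMatrices:
    """AR(1) whitening transform of the design and response.

    Within each pixel (ordered by date) the first row is scaled by
    sqrt(1 - rho^2) and each later row becomes r_t - rho r_{t-1}; the
    transform is the Cholesky factor of the AR(1) inverse correlation (up
    to a 1/sqrt(1-rho^2) scale), so OLS on the transformed data equals GLS
    under the AR(1) correlation.
    """
    rho = ar.rho
    group = np.asarray(ar.group)
    if group.shape[0] != design.X.shape[0]:
        raise ValueError("group length must match design rows")
    firsts = np.ones(len(group), dtype=bool)
    firsts[1:] = group[1:] != group[:-1]
    if len(np.unique(group)) != firsts.sum():
        raise ValueError("groups must be contiguous (sort by pixel, date first)")
    c = np.sqrt(1.0 - rho**2)
    Xw = design.X.copy()
    yw = design.y.copy()
    Xw[~firsts] -= rho * design.X[:-1][~firsts[1:]]
    yw[~firsts] -= rho * design.y[:-1][~firsts[1:]]
    Xw[firsts] *= c
    yw[firsts] *= c
    return DesignMatrices(
        X=Xw, y=yw, terms=design.terms, penalties=design.penalties,
        col_labels=design.col_labels, group=design.group,
        has_factor=design.has_factor, table_refs=design.table_refs,
    )


# ---------------------------------------------------------------------------
# the two model fits


def _fit_pipeline(table: pd.DataFrame, specs, config: ModelConfig, event_factor: bool) -> FittedGAM:
    design = assemble_design(table, specs, config, event_factor=event_factor)
    lam = select_lambda_reml(design, criterion=config.criterion)
    fit0 = fit_penalized(design, lam, rho=0.0, config=config)
    if config.rho_mode in (None, "none"):
        fit0.criterion_value = _criterion_value(design, lam, config)
        return fit0
    rho = estimate_rho(fit0, mode=config.rho_mode)
    if abs(rho) < 1e-12:
        return fit0
    dw = whiten_ar1(design, ARSpec(rho, design.group))
    lam_w = select_lambda_reml(dw, criterion=config.criterion)
    fit = fit_penalized(dw, lam_w, rho=rho, config=config)
    fit.criterion_value = _criterion_value(dw, lam_w, config)
    return fit


def _criterion_value(design, lam, config) -> float:
    XtX = design.X.T @ design.X
    Xty = design.X.T @ design.y
    yty = float(design.y @ design.y)
    groups = _penalty_groups(design)
    mp = design.X.shape[1] - sum(r for _, _, r in groups)
    if config.criterion == "gcv":
        return _gcv_score(design, XtX, Xty, yty, np.log(lam))
    return _reml_score(design, XtX, Xty, yty, groups, mp, np.log(lam))


def fit_eq1(table: pd.DataFrame, config: ModelConfig | None = None) -> FittedGAM:
    """Fit the spatio-temporal trend model (year + month + space + tensors)."""
    config = config or ModelConfig()
    return _fit_pipeline(table, eq1_specs(table, config), config, event_factor=False)


def fit_eq2(table: pd.DataFrame, config: ModelConfig | None = None) -> FittedGAM:
    """Fit the pre/post event model with by-factor smooths.

    The event factor is treatment coded ("pre" the reference), so the
    coefficient on ``war[post]`` is the additive step in mean GPP after the
    cutoff, with its standard error from the posterior covariance.
    """
    config = config or ModelConfig()
    if "war" not in table.columns:
        raise ValueError("table has no 'war' column; run label_event first")
    return _fit_pipeline(table, eq2_specs(table, config), config, event_factor=True)
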