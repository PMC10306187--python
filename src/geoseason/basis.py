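"""Penalized spline and low-rank Gaussian-process bases.

Every smooth term in the additive model is represented by a
:class:`BasisBlock`: a design matrix, one or more quadratic penalty
matrices, and the identifiability (sum-to-zero) transform that was applied.
Supported term types:

* cardinal natural cubic regression splines (knots at quantiles of the
  unique covariate values; penalty = integrated squared second derivative),
* cyclic cubic regression splines whose value, first and second derivative
  match at the period ends (used for month-of-year),
* low-rank Gaussian-process smooths of longitude/latitude built by
  Nystrom projection onto a Matern(3/2) kernel at farthest-point knots,
* tensor-product interactions (row-wise Kronecker; one penalty per margin),
* factor-"by" copies whose design rows are zeroed outside the factor level.

The design/penalty construction follows the standard cubic-spline
interpolation identities: writing the spline through values beta at the
knots with second derivatives gamma, the natural (or cyclic) end conditions
give B gamma = D beta for banded B, D, so gamma = B^{-1} D beta and the
roughness penalty integral f''(x)^2 dx = beta' D' B^{-1} D beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, qr

__all__ = [
    "SmoothSpec",
    "BasisBlock",
    "crs_basis",
    "cyclic_basis",
    "gp_basis",
    "tensor_interaction",
    "by_factor",
    "apply_sum_to_zero",
    "haversine_km",
    "matern32",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# containers


@dataclass
class SmoothSpec:
    """Declarative description of one smooth term."""

    kind: str  # crs | cyclic | gp | tensor
    covariates: tuple
    k: int = 10
    period: float | None = None
    by: str | None = None
    gp_range: float | None = None  # km (or degrees in "degrees" mode)
    distance_mode: str = "km"
    marginals: tuple = ()  # tensor only

    def __post_init__(self):
        if self.kind != "tensor" and self.k < 3:
            raise ValueError("basis dimension k must be >= 3")
        if self.kind == "cyclic" and (self.period is None or self.period <= 0):
            raise ValueError("cyclic smooth requires a positive period")
        if self.kind == "tensor" and len(self.marginals) < 2:
            raise ValueError("tensor smooth requires >= 2 marginal specs")


@dataclass
class BasisBlock:
    """Design matrix + penalties + evaluation state for one smooth term.

    ``X`` is the constrained design (n x p).  ``penalties`` holds one or
    more symmetric PSD p x p matrices, each with its own smoothing
    parameter.  ``constraint`` is the p_raw x p transform from the raw
    basis; ``evaluate(values)`` rebuilds constrained design rows at new
    covariate values using the stored knots/kernel state.
    """

    label: str
    X: np.ndarray
    penalties: list
    constraint: np.ndarray | None = None
    _evaluator: object = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def evaluate_raw(self, *values) -> np.ndarray:
        if self._evaluator is None:
            raise ValueError(f"term {self.label!r} does not support evaluation at new values")
        return self._evaluator(*values)

    def evaluate(self, *values) -> np.ndarray:
        raw = self.evaluate_raw(*values)
        if self.constraint is not None:
            raw = raw @ self.constraint
        return raw


def apply_sum_to_zero(block: BasisBlock) -> BasisBlock:
    """Impose the sum-to-zero identifiability constraint on a block.

    The fitted contribution of the constrained term sums to zero over the
    training rows, which frees the model intercept.  Implemented by
    projecting onto the null space of the column-sum constraint (via the
    complete QR of the constraint vector) and dropping one dimension.
    """
    c = block.X.sum(axis=0)[:, None]  # p x 1
    Q, _ = qr(c, mode="full")
    Z = Q[:, 1:]
    pens = [Z.T @ S @ Z for S in block.penalties]
    pens = [0.5 * (S + S.T) for S in pens]
    prior = block.constraint
    constraint = Z if prior is None else prior @ Z
    return replace(block, X=block.X @ Z, penalties=pens, constraint=constraint)


# ---------------------------------------------------------------------------
# cubic regression spline (natural end conditions)


def _crs_matrices(knots: np.ndarray):
    """Banded B (k-2 x k-2) and D (k-2 x k) of the natural-spline identities."""
    k = len(knots)
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    return B, D


class _CRSEvaluator:
    def __init__(self, knots: np.ndarray, F: np.ndarray):
        self.knots = knots
        self.F = F  # k x k map beta -> second derivatives (zero end rows)

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        t, F = self.knots, self.F
        k = len(t)
        X = np.zeros((len(x), k))
        inside = np.clip(x, t[0], t[-1])
        j = np.clip(np.searchsorted(t, inside, side="right") - 1, 0, k - 2)
        h = t[j + 1] - t[j]
        dm = t[j + 1] - inside
        dp = inside - t[j]
        am, ap = dm / h, dp / h
        cm = (dm**3 / h - h * dm) / 6.0
        cp = (dp**3 / h - h * dp) / 6.0
        rows = np.arange(len(x))
        X[rows, j] += am
        X[rows, j + 1] += ap
        X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
        # linear extrapolation beyond the boundary knots (natural spline)
        lo, hi = x < t[0], x > t[-1]
        if lo.any():
            d0 = self.derivative(np.array([t[0]]))[0]
            X[lo] += (x[lo] - t[0])[:, None] * d0
        if hi.any():
            d1 = self.derivative(np.array([t[-1]]))[0]
            X[hi] += (x[hi] - t[-1])[:, None] * d1
        return X

    def derivative(self, x) -> np.ndarray:
        """Rows mapping beta to f'(x) (x clamped to the knot range)."""
        x = np.clip(np.atleast_1d(np.asarray(x, dtype=float)), self.knots[0], self.knots[-1])
        t, F = self.knots, self.F
        k = len(t)
        X = np.zeros((len(x), k))
        j = np.clip(np.searchsorted(t, x, side="right") - 1, 0, k - 2)
        h = t[j + 1] - t[j]
        dm = t[j + 1] - x
        dp = x - t[j]
        rows = np.arange(len(x))
        X[rows, j] += -1.0 / h
        X[rows, j + 1] += 1.0 / h
        X += ((-3 * dm**2 / h + h) / 6.0)[:, None] * F[j]
        X += ((3 * dp**2 / h - h) / 6.0)[:, None] * F[j + 1]
        return X


def crs_basis(x, k: int, knots=None, label: str = "crs") -> BasisBlock:
    """Cardinal natural cubic regression spline basis.

    Coefficients are the spline's values at the knots (so evaluating the
    unconstrained basis at its own knots gives the identity).  Default
    knots sit at quantiles of the unique covariate values.
    """
    x = np.asarray(x, dtype=float)
    ux = np.unique(x)
    if knots is None:
        if len(ux) < k:
            raise ValueError(f"need >= {k} distinct values for a k={k} spline, got {len(ux)}")
        knots = np.quantile(ux, np.linspace(0, 1, k))
        knots = np.unique(knots)
        if len(knots) < k:
            raise ValueError("quantile knots collapsed; reduce k")
    else:
        knots = np.asarray(knots, dtype=float)
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        k = len(knots)
    B, D = _crs_matrices(knots)
    cb = cho_factor(B)
    F_inner = cho_solve(cb, D)  # (k-2) x k
    F = np.zeros((k, k))
    F[1:-1] = F_inner
    S = D.T @ F_inner
    S = 0.5 * (S + S.T)
    ev = _CRSEvaluator(knots, F)
    return BasisBlock(label=label, X=ev(x), penalties=[S], _evaluator=ev)


# ---------------------------------------------------------------------------
# cyclic cubic regression spline


def _cyclic_matrices(knots: np.ndarray, period: float):
    """Cyclic analogues of B and D (k x k, indices modulo k)."""
    k = len(knots)
    hs = np.diff(np.append(knots, knots[0] + period))
    B = np.zeros((k, k))
    D = np.zeros((k, k))
    for i in range(k):
        im = (i - 1) % k
        ip = (i + 1) % k
        B[i, i] += (hs[im] + hs[i]) / 3.0
        B[i, ip] += hs[i] / 6.0
        B[i, im] += hs[im] / 6.0
        D[i, im] += 1.0 / hs[im]
        D[i, i] += -1.0 / hs[im] - 1.0 / hs[i]
        D[i, ip] += 1.0 / hs[i]
    return B, D, hs


class _CyclicEvaluator:
    def __init__(self, knots: np.ndarray, period: float, G: np.ndarray):
        self.knots = knots
        self.period = period
        self.G = G  # k x k map beta -> second derivatives at knots
        self.h = np.diff(np.append(knots, knots[0] + period))

    def _locate(self, x):
        t, period = self.knots, self.period
        xw = t[0] + np.mod(np.asarray(x, dtype=float) - t[0], period)
        j = np.clip(np.searchsorted(t, xw, side="right") - 1, 0, len(t) - 1)
        return xw, j

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(x)
        t, G = self.knots, self.G
        k = len(t)
        xw, j = self._locate(x)
        jp = (j + 1) % k
        h = self.h[j]
        upper = t[j] + h
        dm = upper - xw
        dp = xw - t[j]
        am, ap = dm / h, dp / h
        cm = (dm**3 / h - h * dm) / 6.0
        cp = (dp**3 / h - h * dp) / 6.0
        X = np.zeros((len(xw), k))
        rows = np.arange(len(xw))
        X[rows, j] += am
        X[rows, jp] += ap
        X += cm[:, None] * G[j] + cp[:, None] * G[jp]
        return X

    def derivative(self, x) -> np.ndarray:
        x = np.atleast_1d(x)
        t, G = self.knots, self.G
        k = len(t)
        xw, j = self._locate(x)
        jp = (j + 1) % k
        h = self.h[j]
        upper = t[j] + h
        dm = upper - xw
        dp = xw - t[j]
        X = np.zeros((len(xw), k))
        rows = np.arange(len(xw))
        X[rows, j] += -1.0 / h
        X[rows, jp] += 1.0 / h
        X += ((-3 * dm**2 / h + h) / 6.0)[:, None] * G[j]
        X += ((3 * dp**2 / h - h) / 6.0)[:, None] * G[jp]
        return X


def cyclic_basis(m, k: int, period: float, lower: float | None = None, label: str = "cyclic") -> BasisBlock:
    """Cyclic cubic regression spline basis (value, f', f'' match at wrap).

    Knots are evenly spaced over one period starting at *lower* (default:
    min of the data).  Coefficients are the spline's values at the k knots;
    the value at lower+period is identified with the value at lower.
    """
    m = np.asarray(m, dtype=float)
    if len(np.unique(m)) < k:
        raise ValueError(f"k={k} exceeds the number of distinct covariate values")
    if lower is None:
        lower = float(np.min(m))
    knots = lower + period * np.arange(k) / k
    B, D, _ = _cyclic_matrices(knots, period)
    G = np.linalg.solve(B, D)
    S = D.T @ G
    S = 0.5 * (S + S.T)
    ev = _CyclicEvaluator(knots, period, G)
    return BasisBlock(label=label, X=ev(m), penalties=[S], _evaluator=ev)


# ---------------------------------------------------------------------------
# low-rank Gaussian-process smooth


def haversine_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distances (km) between lon/lat arrays (n x 2, m x 2)."""
    a = np.deg2rad(np.atleast_2d(a))
    b = np.deg2rad(np.atleast_2d(b))
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    s = np.sin(dlat / 2) ** 2 + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0, 1)))


def _euclid(a, b):
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))


def matern32(d: np.ndarray, rng: float) -> np.ndarray:
    """Matern nu=3/2 correlation with unit marginal variance."""
    q = np.sqrt(3.0) * d / rng
    return (1.0 + q) * np.exp(-q)


def _farthest_point_knots(coords: np.ndarray, k: int, dist) -> np.ndarray:
    """Greedy farthest-point design: good space-filling knot placement."""
    n = len(coords)
    center = coords.mean(axis=0, keepdims=True)
    start = int(np.argmin(dist(coords, center)[:, 0]))
    chosen = [start]
    mind = dist(coords, coords[[start]])[:, 0]
    for _ in range(1, k):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, dist(coords, coords[[nxt]])[:, 0])
    return np.array(chosen)


class _GPEvaluator:
    def __init__(self, knots_xy, U, rng, dist):
        self.knots_xy = knots_xy
        self.U = U
        self.rng = rng
        self.dist = dist

    def __call__(self, lon, lat) -> np.ndarray:
        pts = np.column_stack([np.atleast_1d(lon), np.atleast_1d(lat)])
        K = matern32(self.dist(pts, self.knots_xy), self.rng)
        return K @ self.U


def gp_basis(
    coords,
    k: int,
    rng: float | None = None,
    distance_mode: str = "km",
    label: str = "gp",
    jitter: float = 1e-10,
) -> BasisBlock:
    """Low-rank Gaussian-process basis via Nystrom projection.

    k knots are chosen by farthest-point design over the data; the
    Matern(3/2) kernel at the knots is eigendecomposed and data are
    projected onto the knot eigenbasis.  The penalty is diagonal with the
    inverse eigenvalues, so the coefficient quadratic form approximates the
    GP prior and the implied covariance of the fitted field is the Nystrom
    kernel approximation K_nm K_mm^{-1} K_mn.

    ``rng`` is the Matern range; default = half the maximum inter-point
    distance.  ``distance_mode`` "km" uses great-circle distances on WGS84;
    "degrees" uses raw Euclidean lon/lat distance.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    dist = haversine_km if distance_mode == "km" else _euclid
    uniq = np.unique(coords, axis=0)
    if len(uniq) < k:
        warnings.warn(f"only {len(uniq)} unique sites; reducing gp k from {k}")
        k = len(uniq)
    if rng is None:
        sub = uniq if len(uniq) <= 500 else uniq[np.linspace(0, len(uniq) - 1, 500).astype(int)]
        rng = 0.5 * float(dist(sub, sub).max())
        if rng <= 0:
            raise ValueError("degenerate coordinates: zero spatial extent")
    idx = _farthest_point_knots(uniq, k, dist)
    knots_xy = uniq[idx]
    for attempt in range(2):
        Kmm = matern32(dist(knots_xy, knots_xy), rng)
        Kmm[np.diag_indices_from(Kmm)] += jitter
        w, V = np.linalg.eigh(Kmm)
        if w[0] > -1e-8 * w[-1]:
            break
        if attempt == 0:  # duplicate/near-duplicate knots: jitter and retry once
            rs = np.random.default_rng(0)
            knots_xy = knots_xy + 1e-8 * rs.standard_normal(knots_xy.shape)
        else:
            raise ValueError("knot kernel matrix is not positive definite")
    keep = w > 1e-10 * w[-1]
    w, V = w[keep], V[:, keep]
    # scale the eigenbasis so the implied field covariance is the Nystrom
    # approximation K_nm K_mm^{-1} K_mn under prior Cov(beta) = diag(w)
    ev = _GPEvaluator(knots_xy, V / w[None, :], rng, dist)
    S = np.diag(1.0 / w)
    return BasisBlock(label=label, X=ev(coords[:, 0], coords[:, 1]), penalties=[S], _evaluator=ev)


# ---------------------------------------------------------------------------
# tensor products and by-factor smooths


class _TensorEvaluator:
    def __init__(self, a: BasisBlock, b: BasisBlock):
        self.a, self.b = a, b

    def __call__(self, *values) -> np.ndarray:
        na = _n_args(self.a)
        Xa = self.a.evaluate(*values[:na])
        Xb = self.b.evaluate(*values[na:])
        return _row_kron(Xa, Xb)


def _n_args(block: BasisBlock) -> int:
    return 2 if isinstance(block._evaluator, (_GPEvaluator,)) else 1


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def tensor_interaction(a: BasisBlock, b: BasisBlock, label: str | None = None) -> BasisBlock:
    """Tensor-product interaction of two basis blocks.

    Design = row-wise Kronecker product (a-major column order); two
    penalties, S_a (x) I and I (x) S_b, each with its own smoothing
    parameter, penalizing roughness along each margin.
    """
    if a.X.shape[0] != b.X.shape[0]:
        raise ValueError("marginal designs have different numbers of rows")
    pa, pb = a.p, b.p
    X = _row_kron(a.X, b.X)
    Sa = sum(a.penalties) if len(a.penalties) > 1 else a.penalties[0]
    Sb = sum(b.penalties) if len(b.penalties) > 1 else b.penalties[0]
    pens = [np.kron(Sa, np.eye(pb)), np.kron(np.eye(pa), Sb)]
    lab = label or f"te({a.label},{b.label})"
    return BasisBlock(label=lab, X=X, penalties=pens, _evaluator=_TensorEvaluator(a, b))


def by_factor(block: BasisBlock, indicator, label: str | None = None) -> BasisBlock:
    """Zero a block's design rows outside one factor level.

    The penalty is unchanged; calling this once per level yields the usual
    factor-"by" smooth copies, which have disjoint nonzero rows.
    """
    ind = np.asarray(indicator, dtype=float)
    if ind.shape[0] != block.X.shape[0]:
        raise ValueError("indicator length must match design rows")
    nlev = len(np.unique(ind))
    if nlev < 2:
        warnings.warn("by-factor indicator has a single level; block returned unchanged")
        if ind.min() == 0:
            warnings.warn("all-zero indicator produces a degenerate (zero) design")
    X = block.X * ind[:, None]
    return replace(block, X=X, label=label or f"{block.label}:by")
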