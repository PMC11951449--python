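"""Spline bases, DLNM cross-basis, lag-cumulative reduction and ERF curves.

The exposure dimension uses a quadratic B-spline with knots at fixed
percentiles of the observed exposure (no intercept column, which is absorbed
by the regression intercept), and the lag dimension a natural cubic spline of
lag 0..L with interior knots equally spaced on the log scale, including an
intercept column.  Cumulating the fitted cross-basis coefficients over the
lag dimension yields the low-dimensional coefficient vector of the overall
cumulative exposure-response function (ERF) together with its covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm


# ---------------------------------------------------------------------------
# elementary spline bases
# ---------------------------------------------------------------------------

def _bspline_design(x, degree, interior_knots, boundary):
    """Full B-spline design matrix (with intercept), extrapolating linearly
    in the B-spline sense outside the boundary knots."""
    a, b = boundary
    t = np.concatenate([
        np.repeat(a, degree + 1),
        np.sort(np.asarray(interior_knots, dtype=float)),
        np.repeat(b, degree + 1),
    ])
    x = np.asarray(x, dtype=float)
    return BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()


class NaturalSpline:
    """Natural cubic spline basis with the conventional construction:
    cubic B-splines constrained to zero second derivative at the boundary
    knots, linear extrapolation beyond them.

    Without an intercept column the basis spans ``len(interior_knots) + 1``
    columns; with it, one more.
    """

    def __init__(self, interior_knots, boundary, intercept=False):
        self.interior_knots = np.sort(np.asarray(interior_knots, dtype=float))
        self.boundary = (float(boundary[0]), float(boundary[1]))
        self.intercept = bool(intercept)
        a, b = self.boundary
        if np.any((self.interior_knots <= a) | (self.interior_knots >= b)):
            raise ValueError("interior knots must lie strictly inside the boundary")
        self._t = np.concatenate([
            np.repeat(a, 4), self.interior_knots, np.repeat(b, 4)])
        m = len(self.interior_knots) + 4
        # second derivatives of each cubic B-spline at the two boundaries
        const = np.empty((2, m))
        for j in range(m):
            coef = np.zeros(m)
            coef[j] = 1.0
            d2 = BSpline(self._t, coef, 3).derivative(2)
            const[0, j] = d2(a)
            const[1, j] = d2(b)
        self._drop_first = not self.intercept
        if self._drop_first:
            const = const[:, 1:]
        # null-space projector of the boundary-curvature constraints
        q, _ = np.linalg.qr(const.T, mode="complete")
        self._proj = q[:, 2:]

    @property
    def n_cols(self):
        return self._proj.shape[1]

    def _raw(self, x, deriv=0):
        x = np.asarray(x, dtype=float)
        m = len(self._t) - 4
        if deriv == 0:
            d = BSpline.design_matrix(np.clip(x, *self.boundary),
                                      self._t, 3).toarray()
        else:
            d = np.empty((len(x), m))
            for j in range(m):
                coef = np.zeros(m)
                coef[j] = 1.0
                d[:, j] = BSpline(self._t, coef, 3).derivative(deriv)(
                    np.clip(x, *self.boundary))
        return d[:, 1:] if self._drop_first else d

    def __call__(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        a, b = self.boundary
        inside = self._raw(x) @ self._proj
        lo, hi = x < a, x > b
        if lo.any() or hi.any():
            # first-order Taylor extension => exactly linear beyond boundary
            for mask, bound in ((lo, a), (hi, b)):
                if mask.any():
                    v0 = (self._raw([bound]) @ self._proj)[0]
                    d0 = (self._raw([bound], deriv=1) @ self._proj)[0]
                    inside[mask] = v0 + np.outer(x[mask] - bound, d0)
        return inside


def spline_basis(x, kind="bspline", degree=2, interior_knots=(), boundary=None):
    """Spline design matrix without an intercept column.

    ``bspline``: ``degree + len(interior_knots)`` columns (the first basis
    function of the full B-spline basis is dropped).  ``natural``: natural
    cubic spline with ``len(interior_knots) + 1`` columns.
    """
    x = np.asarray(x, dtype=float)
    if boundary is None:
        boundary = (np.nanmin(x), np.nanmax(x))
    interior_knots = np.sort(np.asarray(interior_knots, dtype=float))
    if len(interior_knots) and (
            interior_knots.min() <= boundary[0] or interior_knots.max() >= boundary[1]):
        raise ValueError("boundary must enclose the interior knots")
    finite = np.isfinite(x)
    if np.any((x[finite] < boundary[0]) | (x[finite] > boundary[1])):
        warnings.warn("values outside the boundary knots: extrapolating",
                      RuntimeWarning, stacklevel=2)
    if kind == "bspline":
        return _bspline_design(x, degree, interior_knots, boundary)[:, 1:]
    if kind == "natural":
        return NaturalSpline(interior_knots, boundary)(x)
    raise ValueError(f"unknown spline kind {kind!r}")


def log_lag_knots(max_lag, n_knots):
    """Interior lag knots equally spaced on the log scale in (1, max_lag):
    ``exp(k/(n+1) * log(max_lag))`` for k = 1..n."""
    if max_lag <= 1:
        raise ValueError("max_lag must exceed 1")
    if n_knots >= max_lag:
        raise ValueError("n_knots must be smaller than max_lag")
    k = np.arange(1, n_knots + 1)
    return np.exp(k / (n_knots + 1) * np.log(max_lag))


# ---------------------------------------------------------------------------
# cross-basis
# ---------------------------------------------------------------------------

@dataclass
class CrossBasisSpec:
    """Parametrisation of the bi-dimensional exposure-lag basis.

    The exposure dimension is resolved against an observed series via
    :meth:`resolve`, which freezes the knot values and boundary so that the
    same basis can be re-evaluated on any grid.
    """

    exposure_degree: int = 2
    exposure_knot_percentiles: tuple = (10.0, 75.0, 90.0)
    exposure_boundary: tuple | None = None
    exposure_knots: tuple | None = None
    max_lag: int = 21
    n_lag_knots: int = 3
    lag_knot_rule: str = "log-equal"

    def __post_init__(self):
        pct = np.asarray(self.exposure_knot_percentiles, dtype=float)
        if np.any(np.diff(pct) <= 0) or pct.min() <= 0 or pct.max() >= 100:
            raise ValueError(
                "exposure_knot_percentiles must be strictly increasing in (0, 100)")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")

    def resolve(self, x):
        """Freeze exposure knots/boundary from an observed series."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        knots = np.percentile(x, self.exposure_knot_percentiles)
        return CrossBasisSpec(
            exposure_degree=self.exposure_degree,
            exposure_knot_percentiles=tuple(self.exposure_knot_percentiles),
            exposure_boundary=(float(x.min()), float(x.max())),
            exposure_knots=tuple(knots),
            max_lag=self.max_lag,
            n_lag_knots=self.n_lag_knots,
            lag_knot_rule=self.lag_knot_rule,
        )

    @property
    def resolved(self):
        return self.exposure_knots is not None and self.exposure_boundary is not None

    @property
    def n_exposure(self):
        """Exposure-basis dimension p (no intercept column)."""
        return self.exposure_degree + len(self.exposure_knot_percentiles)

    @property
    def n_lag(self):
        """Lag-basis dimension q (natural spline with intercept)."""
        return self.n_lag_knots + 2 if self.max_lag > 1 else 1

    def exposure_basis(self, x):
        if not self.resolved:
            raise ValueError("spec not resolved against an exposure series")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return spline_basis(x, "bspline", self.exposure_degree,
                                self.exposure_knots, self.exposure_boundary)

    def lag_basis(self):
        """Natural-spline lag basis evaluated at lags 0..max_lag, including
        an intercept column."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        if self.max_lag == 1:
            return np.ones((2, 1))
        ns = NaturalSpline(log_lag_knots(self.max_lag, self.n_lag_knots),
                           (0.0, float(self.max_lag)), intercept=True)
        return ns(lags)


def build_crossbasis(x, spec: CrossBasisSpec):
    """Cross-basis matrix (T x p*q).  Entry (t, j*q+k) is
    sum_l exposure_basis_j(x[t-l]) * lag_basis_k(l).  The first ``max_lag``
    rows are incomplete and returned as NaN."""
    x = np.asarray(x, dtype=float)
    if not spec.resolved:
        spec = spec.resolve(x)
    if len(x) <= spec.max_lag:
        raise ValueError("series shorter than max_lag")
    E = spec.exposure_basis(x)            # T x p
    L = spec.lag_basis()                  # (max_lag+1) x q
    T, p = E.shape
    q = L.shape[1]
    cb = np.zeros((T, p, q))
    for lag in range(spec.max_lag + 1):
        shifted = np.empty_like(E)
        shifted[:lag] = np.nan
        shifted[lag:] = E[:T - lag]
        cb += shifted[:, :, None] * L[lag][None, None, :]
    return cb.reshape(T, p * q)


def reduction_matrix(spec: CrossBasisSpec):
    """Overall-cumulative reduction M (p x p*q): lag basis summed over lags,
    Kronecker-combined with the identity over exposure-basis columns."""
    c = spec.lag_basis().sum(axis=0)      # q
    return np.kron(np.eye(spec.n_exposure), c[None, :])


@dataclass
class ReducedCoef:
    """Reduced (overall cumulative) ERF coefficients for one location/age."""

    location: object
    age_group: object
    theta: np.ndarray
    S: np.ndarray
    age_value: float | None = None
    spec: CrossBasisSpec | None = field(default=None, repr=False)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (self.theta.size, self.theta.size):
            raise ValueError("S must be square with the dimension of theta")


def reduce_coefs(full_coefs, full_vcov, spec: CrossBasisSpec,
                 location=None, age_group=None):
    """Cumulate cross-basis coefficients over the lag dimension.

    Returns a :class:`ReducedCoef` with theta = M @ full_coefs and
    S = M @ full_vcov @ M.T.
    """
    full_coefs = np.asarray(full_coefs, dtype=float)
    full_vcov = np.asarray(full_vcov, dtype=float)
    pq = spec.n_exposure * spec.n_lag
    if full_coefs.shape != (pq,):
        raise ValueError(f"expected coefficient vector of length {pq}, "
                         f"got {full_coefs.shape}")
    if full_vcov.shape != (pq, pq):
        raise ValueError(f"expected {pq}x{pq} covariance, got {full_vcov.shape}")
    m = reduction_matrix(spec)
    return ReducedCoef(location, age_group, m @ full_coefs,
                       m @ full_vcov @ m.T, spec=spec)


def erf_curve(coef, spec: CrossBasisSpec, grid, center, level=0.95):
    """Overall cumulative exposure-response curve on a grid, centred so that
    log-RR(center) = 0.  Returns a DataFrame (exposure, logrr, se, lo, hi)."""
    grid = np.asarray(grid, dtype=float)
    b = spec.exposure_basis(grid) - spec.exposure_basis([center])
    theta, S = np.asarray(coef.theta), np.asarray(coef.S)
    logrr = b @ theta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", b, S, b), 0.0))
    z = norm.ppf(0.5 + level / 2)
    return pd.DataFrame({
        "exposure": grid,
        "logrr": logrr,
        "se": se,
        "lo": logrr - z * se,
        "hi": logrr + z * se,
    })
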