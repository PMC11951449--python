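"""Spatial extrapolation of BLUP residuals by ordinary kriging.

The realised city random effects (BLUP residuals) carry spatial structure
not explained by the meta-regression fixed effects.  Each residual dimension
is kriged independently: an empirical semivariogram (Matheron estimator) is
fitted with a Gaussian-with-nugget model by weighted least squares, and
ordinary kriging (weights constrained to sum to one, unknown constant mean)
predicts the residual and its variance at unobserved locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform


@dataclass
class VariogramModel:
    """Gaussian semivariogram gamma(h) = nugget + psill*(1 - exp(-(h/range)^2))."""

    nugget: float
    partial_sill: float
    range_param: float
    model: str = "gaussian"

    def __post_init__(self):
        if self.nugget < 0 or self.partial_sill < 0 or self.range_param <= 0:
            raise ValueError("variogram parameters must be non-negative "
                             "(range strictly positive)")

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        return self.nugget + self.partial_sill * (
            1.0 - np.exp(-((h / self.range_param) ** 2)))

    @property
    def sill(self):
        return self.nugget + self.partial_sill


def empirical_semivariogram(points, values, n_bins=15, max_dist=None):
    """Classical Matheron estimator binned by distance.

    Returns a DataFrame (dist, semivariance, n_pairs); empty bins dropped.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    d = pdist(points)
    if max_dist is None:
        max_dist = d.max() / 2
    sq = pdist(values[:, None], metric="sqeuclidean") / 2.0
    edges = np.linspace(0, max_dist, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= max_dist
    rows = []
    for b in range(n_bins):
        m = keep & (which == b)
        if not m.any():
            continue
        rows.append(((edges[b] + edges[b + 1]) / 2,
                     float(sq[m].mean()), int(m.sum())))
    return pd.DataFrame(rows, columns=["dist", "semivariance", "n_pairs"])


def fit_variogram(empirical: pd.DataFrame, model="gaussian") -> VariogramModel:
    """Weighted least squares (weights = pair counts) with non-negativity
    constraints on nugget and partial sill."""
    if model != "gaussian":
        raise ValueError("only the gaussian model is implemented")
    if len(empirical) < 3:
        raise ValueError("need at least 3 non-empty semivariogram bins")
    h = empirical["dist"].to_numpy()
    g = empirical["semivariance"].to_numpy()
    w = np.sqrt(empirical["n_pairs"].to_numpy(dtype=float))

    def resid(par):
        nug, psill, rng = par
        return w * (nug + psill * (1 - np.exp(-((h / rng) ** 2))) - g)

    gmax = max(g.max(), 1e-12)
    hmax = h.max()
    best = None
    for r0 in (hmax / 4, hmax / 2, hmax):
        x0 = [max(g[0] / 2, 1e-10), max(gmax - g[0] / 2, 1e-10), r0]
        # a Gaussian range beyond the sampled distances is unidentifiable,
        # so the range is capped at three times the largest bin distance
        sol = least_squares(resid, x0,
                            bounds=([0, 0, hmax * 1e-4],
                                    [np.inf, np.inf, hmax * 3]))
        if best is None or sol.cost < best.cost:
            best = sol
    nug, psill, rng = best.x
    if psill + nug <= 1e-12:
        warnings.warn("degenerate variogram fit (zero sill): kriging will "
                      "fall back to the mean", RuntimeWarning, stacklevel=2)
    return VariogramModel(float(nug), float(psill), float(rng), model)


def krige(model: VariogramModel, points, values, targets, method="ordinary"):
    """Ordinary (or simple, zero-mean) kriging of one scalar field.

    Returns (predictions, variances) at the target coordinates.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 observed points")

    gamma = model(squareform(pdist(points)))
    np.fill_diagonal(gamma, 0.0)
    g0 = model(cdist(points, targets))          # n x m
    # a coinciding target interpolates its own point exactly
    g0[cdist(points, targets) == 0] = 0.0

    if method == "ordinary":
        a = np.zeros((n + 1, n + 1))
        a[:n, :n] = gamma
        a[n, :n] = 1.0
        a[:n, n] = 1.0
        rhs = np.vstack([g0, np.ones(targets.shape[0])])
        try:
            sol = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("singular kriging system: jitter applied",
                          RuntimeWarning, stacklevel=2)
            a[:n, :n] += 1e-10 * np.eye(n)
            sol = np.linalg.solve(a, rhs)
        w, mu = sol[:n], sol[n]
        pred = w.T @ values
        var = np.einsum("im,im->m", w, g0) + mu
    elif method == "simple":
        # covariance form about a known zero mean
        c = model.sill - gamma
        np.fill_diagonal(c, model.sill)
        c0 = model.sill - g0
        try:
            w = np.linalg.solve(c, c0)
        except np.linalg.LinAlgError:
            warnings.warn("singular kriging system: jitter applied",
                          RuntimeWarning, stacklevel=2)
            w = np.linalg.solve(c + 1e-10 * np.eye(n), c0)
        pred = w.T @ values
        var = model.sill - np.einsum("im,im->m", w, c0)
    else:
        raise ValueError("method must be 'ordinary' or 'simple'")
    return pred, np.maximum(var, 0.0)


@dataclass
class KrigedResidual:
    """Extrapolated residual vector and per-dimension kriging variance for
    one target location."""

    location: object
    xi: np.ndarray
    var: np.ndarray

    @property
    def cov(self):
        return np.diag(self.var)


def krige_residuals(points, residuals, targets, target_ids=None,
                    n_bins=15, method="ordinary", variogram_models=None):
    """Fit a variogram and krige each residual dimension independently.

    ``residuals`` is an n x p matrix of BLUP residuals at the observed
    ``points``; returns (list of KrigedResidual, list of VariogramModel).
    Pre-fitted ``variogram_models`` (one per dimension) skip the fit.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    m, p = targets.shape[0], residuals.shape[1]
    if target_ids is None:
        target_ids = list(range(m))
    preds = np.empty((m, p))
    variances = np.empty((m, p))
    models = []
    for j in range(p):
        if variogram_models is not None:
            model = variogram_models[j]
        else:
            emp = empirical_semivariogram(points, residuals[:, j],
                                          n_bins=n_bins)
            try:
                model = fit_variogram(emp)
            except ValueError:
                model = VariogramModel(0.0, float(np.var(residuals[:, j])),
                                       float(np.max(pdist(points)) / 3))
        models.append(model)
        if model.sill <= 1e-12:
            preds[:, j] = residuals[:, j].mean()
            variances[:, j] = 0.0
            continue
        preds[:, j], variances[:, j] = krige(model, points, residuals[:, j],
                                             targets, method=method)
    return ([KrigedResidual(tid, preds[i], variances[i])
             for i, tid in enumerate(target_ids)], models)
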