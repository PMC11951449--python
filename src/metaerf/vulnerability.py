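"""Composite vulnerability indices from city-level meta-variables.

A potentially large panel of correlated city characteristics is reduced to a
small number K of composite indices by partial least squares (maximising
covariance with the first-stage ERF coefficients) or principal components.
The indices then enter the second-stage meta-regression as fixed-effect
predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA


@dataclass
class ComponentModel:
    """Fitted rotation from P meta-variables to K composite indices."""

    loadings: np.ndarray              # P x K rotation applied to z-scores
    center: np.ndarray
    scale: np.ndarray
    columns: list
    method: str
    K: int
    training_scores: pd.DataFrame = field(repr=False, default=None)


def _standardize(metavars):
    """Z-score columns (ddof=1), median-impute missing values, drop constant
    columns with a warning."""
    v = metavars.copy()
    if v.isna().any().any():
        warnings.warn("missing meta-variables imputed with the column median",
                      RuntimeWarning, stacklevel=3)
        v = v.fillna(v.median())
    sd = v.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant meta-variable columns dropped: {constant}",
                      RuntimeWarning, stacklevel=3)
        v = v.drop(columns=constant)
        sd = sd.drop(constant)
    center = v.mean()
    z = (v - center) / sd
    return z, center.to_numpy(), sd.to_numpy(), list(v.columns)


def _fix_signs(R):
    """Deterministic sign convention: the largest-magnitude loading of each
    component is positive."""
    R = R.copy()
    for k in range(R.shape[1]):
        j = np.argmax(np.abs(R[:, k]))
        if R[j, k] < 0:
            R[:, k] = -R[:, k]
    return R


def fit_components(metavars: pd.DataFrame, response=None, K=6,
                   method="pls") -> ComponentModel:
    """Fit the dimension-reduction model.

    ``metavars`` is a location x P DataFrame.  For PLS, ``response`` is a
    location x p matrix (typically first-stage coefficient vectors averaged
    over age groups within city); PCA ignores it.
    """
    z, center, scale, cols = _standardize(metavars)
    if K > len(cols):
        raise ValueError("K cannot exceed the number of usable meta-variables")
    zv = z.to_numpy()
    if method == "pls":
        if response is None:
            raise ValueError("PLS requires a response matrix")
        y = np.asarray(response, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        pls = PLSRegression(n_components=K, scale=False)
        pls.fit(zv, y - y.mean(axis=0))
        R = _fix_signs(np.asarray(pls.x_rotations_))
    elif method == "pca":
        pca = PCA(n_components=K)
        pca.fit(zv)
        R = _fix_signs(np.asarray(pca.components_.T))
    else:
        raise ValueError(f"unknown method {method!r}")
    scores = pd.DataFrame(zv @ R, index=metavars.index,
                          columns=[f"comp{k+1}" for k in range(K)])
    return ComponentModel(loadings=R, center=center, scale=scale,
                          columns=cols, method=method, K=K,
                          training_scores=scores)


def project(model: ComponentModel, metavars: pd.DataFrame) -> pd.DataFrame:
    """Project (possibly new) locations onto the fitted components."""
    missing = [c for c in model.columns if c not in metavars.columns]
    if missing:
        raise ValueError(f"missing meta-variable columns: {missing}")
    v = metavars[model.columns].copy()
    if v.isna().any().any():
        v = v.fillna(pd.Series(model.center, index=model.columns))
    z = (v.to_numpy() - model.center) / model.scale
    return pd.DataFrame(z @ model.loadings, index=metavars.index,
                        columns=[f"comp{k+1}" for k in range(model.K)])


def component_correlations(model: ComponentModel,
                           metavars: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each original meta-variable with each score."""
    scores = project(model, metavars)
    v = metavars[model.columns].to_numpy(dtype=float)
    s = scores.to_numpy()
    vc = v - v.mean(axis=0)
    sc = s - s.mean(axis=0)
    denom = np.outer(np.sqrt((vc**2).sum(axis=0)),
                     np.sqrt((sc**2).sum(axis=0)))
    corr = (vc.T @ sc) / denom
    return pd.DataFrame(corr, index=model.columns, columns=scores.columns)


def city_average_response(coefs):
    """Average the reduced coefficient vectors over age groups within city,
    giving one response row per city for the PLS fit."""
    rows = {}
    for c in coefs:
        rows.setdefault(c.location, []).append(c.theta)
    index = sorted(rows)
    return pd.DataFrame([np.mean(rows[k], axis=0) for k in index],
                        index=index)
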