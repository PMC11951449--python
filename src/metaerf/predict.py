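"""Composition of full ERF predictions at unobserved locations.

Prediction proceeds in five steps: (i) project the target's meta-variables
onto the fitted vulnerability components, (ii) predict the fixed-effect part
of the coefficients from the meta-regression, (iii) extrapolate the city
random effect by kriging of the BLUP residuals, (iv) sum fixed and random
parts, and (v) sum their covariances (fixed and random effects are
independent in the mixed-model framework).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kriging import krige_residuals
from .metareg import MetaFit, predict_fixed
from .vulnerability import ComponentModel, project


@dataclass
class PredictedERF:
    """Predicted reduced ERF coefficients for one (location, age group)."""

    location: object
    age_group: object
    theta: np.ndarray
    cov: np.ndarray
    x_row: np.ndarray = field(default=None, repr=False)
    mmt: float | None = None
    mmt_percentile: float | None = None
    mmt_flat: bool = False


def predict_unobserved(fit: MetaFit, component_model: ComponentModel,
                       blup_result, locations, metavars, age_values,
                       target_ids=None, kriging_method="ordinary",
                       n_bins=15, variogram_models=None):
    """Predict ERF coefficients at target (default: unobserved) locations.

    Parameters
    ----------
    blup_result : BLUPs from the meta-regression on observed cities; their
        residuals are the kriged field.
    locations : DataFrame with columns (location, x_km, y_km, observed).
    metavars : DataFrame of meta-variables indexed by location (must cover
        the targets).
    age_values : mapping (location, age_group) -> age value for the rows to
        predict.
    """
    loc = locations.set_index("location")
    if target_ids is None:
        target_ids = list(loc.index[~loc["observed"]])
    missing = [t for t in target_ids if t not in metavars.index]
    if missing:
        raise ValueError(f"targets without meta-variables: {missing}")

    scores = project(component_model, metavars.loc[target_ids])

    obs_cities = list(blup_result.xi)
    obs_xy = loc.loc[obs_cities, ["x_km", "y_km"]].to_numpy()
    resid = np.asarray([blup_result.xi[c] for c in obs_cities])
    target_xy = loc.loc[target_ids, ["x_km", "y_km"]].to_numpy()
    kriged, vmodels = krige_residuals(obs_xy, resid, target_xy,
                                      target_ids=target_ids,
                                      method=kriging_method, n_bins=n_bins,
                                      variogram_models=variogram_models)
    kriged = {k.location: k for k in kriged}

    preds = []
    for (location, age_group), age in age_values.items():
        if location not in kriged:
            continue
        x = fit.design.row_for(age, scores.loc[location].to_numpy())
        theta_f, cov_f = predict_fixed(fit, x)
        kr = kriged[location]
        preds.append(PredictedERF(
            location=location, age_group=age_group,
            theta=theta_f[0] + kr.xi, cov=cov_f[0] + kr.cov, x_row=x))
    return preds, kriged, vmodels


def find_mmt(pred, spec, exposure, bounds=(1.0, 99.0), n_grid=100):
    """Locate the minimum-mortality temperature of a predicted curve by grid
    search over exposure percentiles, and re-centre the prediction there.

    Returns (mmt value, mmt percentile).  A flat curve returns the midpoint
    of the search bounds with ``mmt_flat`` set.
    """
    exposure = np.asarray(exposure, dtype=float)
    exposure = exposure[np.isfinite(exposure)]
    if np.ptp(exposure) == 0:
        raise ValueError("degenerate exposure distribution")
    pcts = np.linspace(bounds[0], bounds[1], n_grid)
    grid = np.percentile(exposure, pcts)
    b = spec.exposure_basis(grid)
    logrr = b @ np.asarray(pred.theta)
    if np.ptp(logrr) < 1e-12:
        pred.mmt_flat = True
        i = n_grid // 2
    else:
        i = int(np.argmin(logrr))
    pred.mmt = float(grid[i])
    pred.mmt_percentile = float(pcts[i])
    return pred.mmt, pred.mmt_percentile
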