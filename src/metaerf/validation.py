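"""Holdout validation of predicted ERFs against reference BLUPs.

The reference is a classical two-stage analysis of the full set of cities
(first stage through meta-regression); its BLUPs for the holdout cities are
compared to (a) the framework's predictions treating those cities as
unobserved and (b) their raw first-stage estimates.  Errors are root mean
squared differences of log relative risk over an exposure percentile grid,
reported as a relative increase on the RR scale, exp(RMSE) - 1, overall and
restricted to the cold (below the 5th percentile) and heat (above the 95th)
tails.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import predict_targets, run_two_stage

REGIONS = ("total", "cold", "heat")


def holdout_rmse(pred_logrr, ref_logrr, pct_grid, region="total"):
    """exp(RMSE) - 1 between two identically-centred log-RR curves on a
    percentile grid, optionally restricted to the cold/heat tails."""
    pred_logrr = np.asarray(pred_logrr, dtype=float)
    ref_logrr = np.asarray(ref_logrr, dtype=float)
    pct_grid = np.asarray(pct_grid, dtype=float)
    if pred_logrr.shape != ref_logrr.shape or pred_logrr.shape != pct_grid.shape:
        raise ValueError("curves and grid must share the same shape")
    if region == "total":
        mask = np.ones_like(pct_grid, dtype=bool)
    elif region == "cold":
        mask = pct_grid < 5.0
    elif region == "heat":
        mask = pct_grid > 95.0
    else:
        raise ValueError("region must be 'total', 'cold' or 'heat'")
    rmse = np.sqrt(np.mean((pred_logrr[mask] - ref_logrr[mask]) ** 2))
    return float(np.exp(rmse) - 1.0)


def run_validation(study, holdout_ids=None, K=6, spec=None,
                   pct_grid=np.arange(1.0, 100.0)):
    """Full validation study on one synthetic study.

    Returns (per_city, summary): per-city rows (location, age_group, region,
    estimator, rmse) and their means per (age_group, region, estimator).
    """
    loc = study.locations
    if holdout_ids is None:
        holdout_ids = list(loc.loc[~loc["observed"], "location"])

    # reference: two-stage fit using every city's data
    ts_all = run_two_stage(study, K=K, locations=list(loc["location"]),
                           spec=spec)
    # framework prediction treating the holdout cities as unobserved
    # (first-stage fits reused from the full run)
    obs_coefs = [c for c in ts_all.coefs
                 if c.location not in set(holdout_ids)]
    ts_obs = run_two_stage(study, K=K, spec=spec, coefs=obs_coefs)
    preds, *_ = predict_targets(study, ts_obs, target_ids=holdout_ids)
    pred_map = {(p.location, p.age_group): p for p in preds}

    ref_blup = {row: ts_all.blups.theta_blup[i]
                for i, row in enumerate(ts_all.blups.rows)}
    fs_map = {(c.location, c.age_group): c for c in ts_all.coefs}

    temps = {l: g["temp"].to_numpy()
             for l, g in study.series[study.series["location"].isin(holdout_ids)]
             .groupby("location")}

    rows = []
    for key, pred in pred_map.items():
        city, age_group = key
        if key not in ref_blup or key not in fs_map:
            continue
        t = temps[city]
        cspec = (spec or fs_map[key].spec).resolve(t)
        grid = np.percentile(t, pct_grid)
        b = cspec.exposure_basis(grid)

        ref_curve = b @ ref_blup[key]
        # centre every curve at the reference curve's minimum
        c0 = int(np.argmin(ref_curve))
        curves = {
            "predicted": b @ pred.theta,
            "first_stage": b @ fs_map[key].theta,
        }
        ref_curve = ref_curve - ref_curve[c0]
        for est, curve in curves.items():
            curve = curve - curve[c0]
            for region in REGIONS:
                rows.append((city, age_group, region, est,
                             holdout_rmse(curve, ref_curve, pct_grid, region)))
    per_city = pd.DataFrame(rows, columns=["location", "age_group", "region",
                                           "estimator", "rmse"])
    summary = (per_city.groupby(["age_group", "region", "estimator"])["rmse"]
               .mean().reset_index())
    return per_city, summary
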