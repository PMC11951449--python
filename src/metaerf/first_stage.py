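"""First-stage quasi-Poisson time-series regressions per (location, age group).

Each series of daily death counts is regressed on the DLNM cross-basis of
temperature, a natural spline of time (7 df per year by default) and
day-of-week indicators, with a log link.  The coefficient covariance is
scaled by the Pearson dispersion (quasi-Poisson).  The cross-basis block is
then cumulated over the lag dimension into the reduced ERF coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import CrossBasisSpec, NaturalSpline, build_crossbasis, reduce_coefs

logger = logging.getLogger(__name__)


@dataclass
class FirstStageFit:
    """Full fit of the first-stage model for one (location, age group)."""

    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    converged: bool
    spec: CrossBasisSpec = field(repr=False)
    cb_slice: slice = field(repr=False)
    n_obs: int = 0

    def reduced(self, location=None, age_group=None):
        sl = self.cb_slice
        return reduce_coefs(self.coef[sl], self.vcov[sl, sl], self.spec,
                            location=location, age_group=age_group)


def _time_spline(n, df):
    """Natural spline of the time index with the requested df (columns);
    interior knots at equally spaced quantiles."""
    t = np.arange(n, dtype=float)
    if df < 2:
        return t[:, None] / n
    probs = np.linspace(0, 1, df + 1)[1:-1]
    knots = np.quantile(t, probs)
    return NaturalSpline(knots, (t[0], t[-1]))(t)


def fit_city_age(series, spec: CrossBasisSpec, time_df_per_year=7,
                 dow=True, extra_confounders=None):
    """Fit the first-stage model to one daily series.

    ``series`` is a DataFrame with columns (date, temp, deaths).  Rows with
    incomplete lag history (the first ``max_lag`` days) are excluded.
    Raises ``ValueError`` on degenerate input (all-zero counts, too short).
    """
    dates = pd.to_datetime(series["date"])
    y = series["deaths"].to_numpy(dtype=float)
    x = series["temp"].to_numpy(dtype=float)
    n_days = (dates.iloc[-1] - dates.iloc[0]).days + 1
    n_years = n_days / 365.25
    if n_days < 729:
        raise ValueError("need at least 2 years of data")
    if not np.any(y > 0):
        raise ValueError("all-zero death counts")

    spec = spec if spec.resolved else spec.resolve(x)
    cb = build_crossbasis(x, spec)
    n_cb = cb.shape[1]

    blocks = [np.ones((len(y), 1)), cb,
              _time_spline(len(y), int(round(time_df_per_year * n_years)))]
    if dow:
        d = pd.get_dummies(dates.dt.dayofweek, drop_first=True)
        blocks.append(d.to_numpy(dtype=float))
    if extra_confounders is not None:
        blocks.append(np.asarray(extra_confounders, dtype=float))
    X = np.column_stack(blocks)

    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y[ok], X[ok], family=sm.families.Poisson())
        res = model.fit(scale="X2", maxiter=100, tol=1e-8)
    converged = bool(getattr(res, "converged", True))
    return FirstStageFit(
        coef=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        dispersion=float(res.scale),
        converged=converged,
        spec=spec,
        cb_slice=slice(1, 1 + n_cb),
        n_obs=int(ok.sum()),
    )


def run_all(study, spec: CrossBasisSpec | None = None, time_df_per_year=7,
            locations=None):
    """Fit every observed (location, age group) series of a study and return
    the reduced coefficients.  Failures are skipped with a logged reason.
    ``locations`` overrides the default set (the observed cities)."""
    spec = spec or CrossBasisSpec()
    if locations is None:
        observed = set(study.locations.loc[study.locations["observed"],
                                           "location"])
    else:
        observed = set(locations)
    out = []
    n_failed = 0
    for (loc, age), df in study.series.groupby(["location", "age_group"],
                                               sort=True):
        if loc not in observed:
            continue
        try:
            fit = fit_city_age(df.sort_values("date"), spec,
                               time_df_per_year=time_df_per_year)
            if not fit.converged:
                raise RuntimeError("IRLS did not converge")
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as err:
            n_failed += 1
            logger.warning("first stage failed for %s / %s: %s", loc, age, err)
            continue
        out.append(fit.reduced(location=loc, age_group=age))
    logger.info("first stage: %d fits kept, %d excluded", len(out), n_failed)
    return out
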