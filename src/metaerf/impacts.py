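"""Attributable burden and age-standardised excess mortality rates.

Daily attributable fractions AF_t = 1 - exp(-logRR(x_t)) are computed from
the overall cumulative ERF centred at the minimum-mortality temperature,
multiplied by the daily death counts and summed over the period
(attributable number, split into cold and heat days).  Excess rates per
100,000 person-years are standardised with reference age weights so that
impacts are comparable across populations with different age structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PER = 100_000.0


@dataclass
class AttributableResult:
    af_series: pd.Series
    an_total: float
    an_cold: float
    an_heat: float
    an_mmt: float
    total_deaths: float

    @property
    def af_total(self):
        return self.an_total / self.total_deaths if self.total_deaths else 0.0


def attributable(series, pred, spec) -> AttributableResult:
    """Daily attributable fractions/numbers for one (location, age group).

    ``series`` has columns (temp, deaths); ``pred`` must carry an ``mmt``
    (see :func:`metaerf.predict.find_mmt`).
    """
    if pred.mmt is None:
        raise ValueError("prediction must be centred at the MMT first")
    temp = series["temp"].to_numpy(dtype=float)
    deaths = series["deaths"].to_numpy(dtype=float)
    b = spec.exposure_basis(temp) - spec.exposure_basis([pred.mmt])
    logrr = b @ np.asarray(pred.theta)
    af = 1.0 - np.exp(-logrr)
    an = af * deaths
    cold, heat = temp < pred.mmt, temp > pred.mmt
    return AttributableResult(
        af_series=pd.Series(af, index=series.index),
        an_total=float(an.sum()),
        an_cold=float(an[cold].sum()),
        an_heat=float(an[heat].sum()),
        an_mmt=float(an[~cold & ~heat].sum()),
        total_deaths=float(deaths.sum()),
    )


def baseline_emulate(annual_deaths, profile, dates):
    """Daily baseline deaths from an annual total and a mean-normalised
    day-of-year profile (366 entries, mean 1)."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (366,):
        raise ValueError("profile must have 366 entries (day of year)")
    if np.any(profile < 0):
        raise ValueError("profile values must be non-negative")
    profile = profile / profile.mean()
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    return pd.Series(annual_deaths / 365.25 * profile[doy - 1], index=dates)


def day_of_year_profile(series):
    """Mean-normalised day-of-year mortality profile from observed series
    (columns date, deaths), pooled over locations."""
    df = series.copy()
    doy = pd.to_datetime(df["date"]).dt.dayofyear
    prof = df.groupby(doy)["deaths"].mean().reindex(range(1, 367))
    prof = prof.interpolate(limit_direction="both")
    return (prof / prof.mean()).to_numpy()


def excess_rate(an, population, period_years):
    """Excess mortality rate per 100,000 person-years."""
    if population <= 0:
        raise ValueError("population must be positive")
    return an / (population * period_years) * PER


def standardize_rate(rates, weights):
    """Age-standardised excess rate: weighted mean of age-group rates with
    reference weights (Eq of the standardised rate).

    ``rates`` and ``weights`` are aligned mappings/Series over age groups.
    """
    rates = pd.Series(rates, dtype=float)
    weights = pd.Series(weights, dtype=float)
    if set(rates.index) != set(weights.index):
        raise ValueError("age groups of rates and weights do not match")
    weights = weights.reindex(rates.index)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    return float((rates * weights).sum() / weights.sum())


def regional_rates(city_rates, city_population, city_region):
    """Population-weighted regional aggregation of city standardised rates."""
    df = pd.DataFrame({"rate": pd.Series(city_rates),
                       "pop": pd.Series(city_population),
                       "region": pd.Series(city_region)})
    return df.groupby("region").apply(
        lambda g: float(np.average(g["rate"], weights=g["pop"])),
        include_groups=False)


def reference_weights(demography):
    """Study-wide average age structure (population shares per age group)."""
    pop = demography.groupby(["location", "age_group"])["population"] \
                    .first().groupby("age_group").sum()
    return pop / pop.sum()
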