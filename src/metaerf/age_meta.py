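"""Continuous age meta-variable for each (location, age group).

Each first-stage coefficient vector is tagged with a representative age of
death for its age group, used as a continuous effect modifier in the
second-stage meta-regression.  The preferred definition is the death-weighted
mean age within the group; fallbacks cover open-ended groups (attained age
implied by remaining life expectancy at the lower bound) and missing death
data (interval midpoint).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def age_meta_variable(bounds, deaths_by_age=None, life_expectancy=None,
                      fallback_upper=100):
    """Representative age of death for an age group.

    Parameters
    ----------
    bounds : (lower, upper) in years; ``upper=None`` marks an open-ended group
        (e.g. 85+).
    deaths_by_age : mapping or Series of single-year age -> death count, or
        None when no single-year data is available.
    life_expectancy : remaining life expectancy (years) at the group's lower
        bound, used for open-ended groups.
    fallback_upper : upper bound substituted for open-ended groups when no
        life expectancy is available.

    Priority: (1) death-weighted mean age over [lower, upper]; (2) open-ended
    group with life expectancy -> lower + remaining expectancy; (3) no death
    data -> midpoint of the interval [lower, upper+1); (4) open-ended with
    deaths but no life expectancy -> death-weighted mean with
    upper = fallback_upper.
    """
    lower, upper = bounds
    if upper is not None and lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    open_ended = upper is None

    if open_ended and life_expectancy is not None:
        return float(lower + life_expectancy)

    if deaths_by_age is not None:
        s = pd.Series(deaths_by_age, dtype=float)
        if (s < 0).any():
            raise ValueError("death counts must be non-negative")
        if s.index.min() < 0 or s.index.max() > 110:
            raise ValueError("ages must lie in [0, 110]")
        u = fallback_upper if open_ended else upper
        s = s[(s.index >= lower) & (s.index <= u)]
        tot = s.sum()
        if tot > 0:
            return float((s.index.to_numpy(dtype=float) * s.to_numpy()).sum() / tot)
        warnings.warn("no deaths in the age group: falling back to the "
                      "interval midpoint", RuntimeWarning, stacklevel=2)

    u = fallback_upper if open_ended else upper
    return float((lower + u + 1) / 2)


def attach_age_values(coefs, demography, age_groups):
    """Fill ``age_value`` on a collection of reduced coefficients from a
    demography table.

    ``demography`` is a DataFrame with columns (location, age_group, age,
    deaths, life_expectancy); single-year rows carry deaths per age, and
    ``life_expectancy`` is the remaining expectancy at the group's lower
    bound (constant within group, may be NaN).  ``age_groups`` maps group
    label -> (lower, upper or None).
    """
    demo = demography.set_index(["location", "age_group"]).sort_index()
    for c in coefs:
        bounds = age_groups[c.age_group]
        try:
            block = demo.loc[(c.location, c.age_group)]
        except KeyError:
            c.age_value = age_meta_variable(bounds)
            continue
        deaths = pd.Series(block["deaths"].to_numpy(),
                           index=block["age"].to_numpy())
        le = block["life_expectancy"].iloc[0]
        le = None if pd.isna(le) else float(le)
        c.age_value = age_meta_variable(bounds, deaths_by_age=deaths,
                                        life_expectancy=le)
    return coefs
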