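"""Synthetic multi-city studies with known ground truth.

The generator emulates the structure of a national multi-city
temperature-mortality study: cities scattered over a country-sized planar
domain, five age groups, a panel of correlated city-level meta-variables,
daily temperature and mortality series, and demography tables.  True reduced
ERF coefficients are generated from the second-stage model itself
(fixed effects from an age spline plus latent vulnerability components, a
spatially correlated city random effect, and an independent city effect),
so every downstream stage can be validated against known truth.

Daily series are generated by inverting the first-stage model: the true
reduced coefficients are expanded into a full cross-basis coefficient set
whose lag-cumulative reduction returns the truth exactly, applied through
the full lag structure with a seasonal term and day-of-week effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .age_meta import age_meta_variable
from .basis import CrossBasisSpec, NaturalSpline, build_crossbasis

DEFAULT_AGE_GROUPS = (
    ("0-44", 0, 44),
    ("45-64", 45, 64),
    ("65-74", 65, 74),
    ("75-84", 75, 84),
    ("85+", 85, None),
)

# fixed effects of the coefficient-generating model: rows = intercept,
# two age-spline columns, three latent vulnerability components;
# columns = the 5 reduced exposure-basis coefficients (low columns load the
# cold end of the curve, high columns the heat end).
DEFAULT_TRUE_BETA = np.array([
    [0.25, 0.02, -0.02, 0.10, 0.45],
    [0.08, 0.00, 0.00, 0.05, 0.25],
    [0.12, 0.00, 0.00, 0.08, 0.40],
    [0.08, 0.00, 0.00, 0.03, 0.12],
    [0.00, 0.02, 0.00, 0.05, -0.08],
    [0.05, 0.00, 0.02, 0.00, 0.10],
])

DEFAULT_TRUE_PSI = np.diag([0.004, 0.001, 0.001, 0.002, 0.006])

# annual death rates per age group, roughly European all-cause levels
_DEATH_RATES = np.array([0.0012, 0.004, 0.013, 0.04, 0.13])
_POP_FRACS = np.array([0.50, 0.25, 0.11, 0.09, 0.05])
_LIFE_EXP = {0: 82.0, 45: 38.0, 65: 20.5, 75: 12.5, 85: 6.5}


@dataclass
class StudyConfig:
    """Conditions of a synthetic multi-city study."""

    n_locations: int = 87
    age_groups: tuple = DEFAULT_AGE_GROUPS
    years: int = 4
    n_metavars: int = 21
    holdout_fraction: float = 0.30
    seed: int = 0
    true_beta: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_BETA.copy())
    true_psi: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_PSI.copy())
    spatial_range_km: float = 200.0
    spatial_sill: float = 0.005
    overdispersion: float = 1.2
    n_latent: int = 3
    start_date: str = "2015-01-01"
    pop_scale: float = 1.0

    def __post_init__(self):
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in [0, 1)")
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        self.true_psi = np.asarray(self.true_psi, dtype=float)
        psi = self.true_psi
        if not np.allclose(psi, psi.T) or np.linalg.eigvalsh(psi).min() < -1e-10:
            raise ValueError("true_psi must be symmetric positive semi-definite")
        bounds = [(lo, up) for _, lo, up in self.age_groups]
        for (l0, u0), (l1, _) in zip(bounds, bounds[1:]):
            if u0 is None or u0 >= l1:
                raise ValueError("age-group bounds must be ordered and "
                                 "non-overlapping")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")

    @property
    def n_coef(self):
        return self.true_beta.shape[1]


@dataclass
class SyntheticStudy:
    config: StudyConfig
    locations: pd.DataFrame
    metavars: pd.DataFrame
    series: pd.DataFrame | None
    demography: pd.DataFrame
    truth: dict

    @property
    def age_group_bounds(self):
        return {lab: (lo, up) for lab, lo, up in self.config.age_groups}


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------

def _gen_locations(config, rng):
    n = config.n_locations
    x = rng.uniform(0, 700, n)
    y = rng.uniform(0, 1000, n)
    lat = 37.0 + y / 111.0
    lon = 8.0 + x / (111.0 * np.cos(np.deg2rad(lat)))
    km = KMeans(n_clusters=min(5, n), n_init=4,
                random_state=int(rng.integers(2**31 - 1)))
    region = km.fit_predict(np.column_stack([x, y]))
    n_holdout = int(np.ceil(n * config.holdout_fraction))
    observed = np.ones(n, dtype=bool)
    if n_holdout:
        observed[rng.choice(n, n_holdout, replace=False)] = False
    return pd.DataFrame({
        "location": [f"city{i:03d}" for i in range(n)],
        "lon": lon, "lat": lat, "x_km": x, "y_km": y,
        "region": [f"region{r}" for r in region],
        "observed": observed,
    })


def _gen_metavars(config, latent, rng):
    """Meta-variables in correlated blocks driven by the latent components."""
    n, P, K = latent.shape[0], config.n_metavars, config.n_latent
    block = np.array_split(np.arange(P), K)
    v = 0.4 * rng.standard_normal((n, P))
    for k, cols in enumerate(block):
        strength = rng.uniform(0.5, 1.0, len(cols)) * rng.choice([-1, 1], len(cols))
        v[:, cols] += np.outer(latent[:, k], strength)
    # heterogeneous units/offsets, as in real socio-economic panels
    v = v * rng.uniform(0.5, 20.0, P) + rng.uniform(-5, 50, P)
    return pd.DataFrame(v, columns=[f"mv{j+1:02d}" for j in range(P)])


def gen_demography(locations, age_groups, seed, rng=None, pop_scale=1.0):
    """Demography table: population, single-year deaths and remaining life
    expectancy at the group lower bound, per (location, age group)."""
    rng = rng or np.random.default_rng(seed)
    rows = []
    for _, loc in locations.iterrows():
        total_pop = float(np.exp(rng.normal(12.2, 0.5))) * pop_scale
        fracs = rng.dirichlet(_POP_FRACS * 120)
        tilt = rng.normal(0.08, 0.02)
        for g, (label, lo, up) in enumerate(age_groups):
            pop = total_pop * fracs[g]
            annual = pop * _DEATH_RATES[g] * np.exp(rng.normal(0, 0.15))
            u = up if up is not None else min(lo + 20, 110)
            ages = np.arange(lo, u + 1)
            w = np.exp(tilt * (ages - lo))
            counts = rng.multinomial(max(int(round(annual)), 1), w / w.sum())
            le = max(_LIFE_EXP.get(lo, max(90 - lo, 2.0)) + rng.normal(0, 0.4),
                     1.0)
            for age, d in zip(ages, counts):
                rows.append((loc["location"], label, int(age), int(d),
                             pop, le))
    return pd.DataFrame(rows, columns=[
        "location", "age_group", "age", "deaths", "population",
        "life_expectancy"])


def _age_values(demography, age_groups):
    """Representative age of death per (location, age group), using the
    death-weighted mean for closed groups and attained life expectancy for
    the open-ended group."""
    vals = {}
    for (loc, label), block in demography.groupby(["location", "age_group"]):
        lo, up = next((l, u) for lab, l, u in age_groups if lab == label)
        deaths = pd.Series(block["deaths"].to_numpy(),
                           index=block["age"].to_numpy())
        le = float(block["life_expectancy"].iloc[0]) if up is None else None
        vals[(loc, label)] = age_meta_variable((lo, up), deaths_by_age=deaths,
                                               life_expectancy=le)
    return vals


def _spatial_field(xy, sill, range_km, p, rng):
    """Gaussian random field per coefficient dimension via Cholesky of a
    Gaussian (squared-exponential) covariance on planar km coordinates."""
    n = xy.shape[0]
    if sill <= 0:
        return np.zeros((n, p))
    h = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    cov = sill * np.exp(-((h / range_km) ** 2)) + 1e-10 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((n, p))


def gen_series(location, true_coef, years, daily_mean, overdispersion, seed,
               spec=None, start_date="2015-01-01"):
    """Daily (date, temp, deaths) table for one (location, age group).

    ``location`` is a mapping with keys ``temp_mean`` and ``temp_amp``.  The
    expected counts follow a log link: baseline ``daily_mean`` times a mild
    winter-peaked seasonal cycle, day-of-week effects, and the true ERF
    applied through the full lag structure.  The full cross-basis
    coefficients are constructed so that their lag-cumulative reduction
    equals ``true_coef`` exactly.
    """
    rng = np.random.default_rng(seed)
    spec = spec or CrossBasisSpec()
    true_coef = np.asarray(true_coef, dtype=float)
    n_days = int(round(years * 365.25))
    pad = spec.max_lag
    total = n_days + pad

    dates = pd.date_range(pd.Timestamp(start_date) - pd.Timedelta(days=pad),
                          periods=total, freq="D")
    doy = dates.dayofyear.to_numpy()
    # annual sinusoid plus AR(1) noise
    season_t = np.cos(2 * np.pi * (doy - 200) / 365.25)
    eps = np.empty(total)
    eps[0] = rng.normal(0, 2.5)
    innov = rng.normal(0, 2.5 * np.sqrt(1 - 0.75**2), total)
    for t in range(1, total):
        eps[t] = 0.75 * eps[t - 1] + innov[t]
    temp = location["temp_mean"] + location["temp_amp"] * season_t + eps

    rspec = spec.resolve(temp)
    if true_coef.size != rspec.n_exposure:
        raise ValueError(
            f"true_coef must have length {rspec.n_exposure}")
    # expand the reduced coefficients into full cross-basis coefficients:
    # lag curve proportional to a smooth decaying weight, rescaled so the
    # lag-cumulative reduction gives back true_coef exactly
    L = rspec.lag_basis()
    w = np.exp(-np.arange(spec.max_lag + 1) / 4.5)
    c, *_ = np.linalg.lstsq(L, w / w.sum(), rcond=None)
    c = c / (L.sum(axis=0) @ c)
    eta = np.outer(true_coef, c).ravel()

    cb = build_crossbasis(temp, rspec)
    erf = cb @ eta
    erf = erf - np.nanmean(erf)
    seasonal = 0.12 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    dow_eff = np.array([0.01, 0.0, 0.0, 0.0, 0.0, 0.005, -0.01])
    lin = np.log(daily_mean) + seasonal + dow_eff[dates.dayofweek] + erf
    mu = np.exp(lin[pad:])

    if overdispersion > 1:
        k = mu.mean() / (overdispersion - 1)
        mu = mu * rng.gamma(k, 1.0 / k, size=mu.size)
    deaths = rng.poisson(mu)
    return pd.DataFrame({
        "date": dates[pad:], "temp": temp[pad:], "deaths": deaths})


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def gen_study(config: StudyConfig, with_series=True) -> SyntheticStudy:
    """Generate a complete synthetic study.

    The true reduced coefficients satisfy the second-stage model exactly
    before noise: theta_ia = X_ia @ true_beta + b_i with X built from the
    age meta-variable spline (knot at 60) and the latent vulnerability
    components, and b_i the sum of a spatially correlated Gaussian field
    and an independent N(0, true_psi) city effect.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_coef

    locations = _gen_locations(config, rng)
    latent = rng.standard_normal((config.n_locations, config.n_latent))
    metavars = _gen_metavars(config, latent, rng)
    metavars.index = locations["location"]
    demography = gen_demography(locations, config.age_groups, None, rng=rng,
                                pop_scale=config.pop_scale)
    age_vals = _age_values(demography, config.age_groups)

    ages = np.array([age_vals[(loc, lab)]
                     for loc in locations["location"]
                     for lab, *_ in config.age_groups])
    age_spline = NaturalSpline([60.0], (ages.min(), ages.max()))

    n_groups = len(config.age_groups)
    k_expected = 1 + age_spline.n_cols + config.n_latent
    if config.true_beta.shape[0] != k_expected:
        raise ValueError(f"true_beta must have {k_expected} rows")

    xy = locations[["x_km", "y_km"]].to_numpy()
    b_spatial = _spatial_field(xy, config.spatial_sill,
                               config.spatial_range_km, p, rng)
    chol_psi = np.linalg.cholesky(config.true_psi
                                  + 1e-12 * np.eye(p))
    b_iid = rng.standard_normal((config.n_locations, p)) @ chol_psi.T
    b = b_spatial + b_iid

    design_rows, theta_rows, idx = [], [], []
    for i, loc in enumerate(locations["location"]):
        for lab, *_ in config.age_groups:
            a = age_vals[(loc, lab)]
            x_row = np.concatenate([[1.0], age_spline([a])[0], latent[i]])
            design_rows.append(x_row)
            theta_rows.append(x_row @ config.true_beta + b[i])
            idx.append((loc, lab, a))
    design = np.asarray(design_rows)
    theta_true = np.asarray(theta_rows)
    truth = {
        "theta": pd.DataFrame(
            theta_true,
            index=pd.MultiIndex.from_tuples([t[:2] for t in idx],
                                            names=["location", "age_group"]),
            columns=[f"theta{j+1}" for j in range(p)]),
        "age_value": {t[:2]: t[2] for t in idx},
        "design": design,
        "latent": latent,
        "b": b,
        "b_spatial": b_spatial,
        "true_beta": config.true_beta,
        "age_spline": age_spline,
    }

    series = None
    if with_series:
        spec = CrossBasisSpec()
        demo_key = demography.groupby(["location", "age_group"])["deaths"] \
                             .sum().to_dict()
        seeds = np.random.SeedSequence(config.seed).spawn(
            config.n_locations * n_groups)
        frames = []
        si = 0
        for i, row in locations.iterrows():
            temp_mean = 18.0 - 0.55 * (row["lat"] - 37.0) + rng.normal(0, 0.8)
            temp_amp = rng.normal(9.0, 1.0)
            loc_info = {"temp_mean": temp_mean, "temp_amp": abs(temp_amp)}
            for g, (lab, *_r) in enumerate(config.age_groups):
                daily = max(demo_key[(row["location"], lab)], 1) / 365.25
                df = gen_series(loc_info, theta_true[i * n_groups + g],
                                config.years, daily, config.overdispersion,
                                seeds[si], spec=spec,
                                start_date=config.start_date)
                df.insert(0, "age_group", lab)
                df.insert(0, "location", row["location"])
                frames.append(df)
                si += 1
        series = pd.concat(frames, ignore_index=True)

    return SyntheticStudy(config=config, locations=locations,
                          metavars=metavars, series=series,
                          demography=demography, truth=truth)
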