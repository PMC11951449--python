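# Methods

## Model

### First stage

For city *i* and age group *a*, daily death counts follow a log-link
quasi-Poisson model

log E[y_iat] = α_ia + f(x_it, ℓ; η_ia) + s(t; φ_ia) + dow(t; γ_ia)

where *f* is a DLNM cross-basis over temperature and lag. The exposure
basis is a quadratic B-spline with interior knots at the 10th/75th/90th
percentiles of the city's own temperature and boundary knots at its observed
min/max (5 columns, no intercept — the model intercept absorbs it). The lag
basis is a natural cubic spline of lag 0..21 **with** an intercept column
and three interior knots at exp(k/4·log 21), k = 1..3 ≈ (2.14, 4.58, 9.81)
days — i.e. equally spaced on log(lag), placed strictly above lag 1. The
time spline uses round(7 × years) df with knots at equally spaced quantiles
of the time index; day-of-week enters as six indicator contrasts. Rows with
incomplete lag history (the first 21 days) are excluded rather than imputed.
The coefficient covariance is scaled by the Pearson dispersion with **no
floor at 1** (the dispersion is used as estimated). IRLS runs to a deviance
tolerance of 1e-8 (max 100 iterations); fits that fail to converge or have
all-zero counts are excluded and logged.

The cross-basis block η̂ is reduced to the overall cumulative ERF by
θ̂ = M η̂, S = M V̂ Mᵀ with M = I₅ ⊗ Cᵀ, C the lag basis summed over lags
0..21. The ERF at exposure x, centred at c, is b(x)ᵀθ − b(c)ᵀθ with
variance (b(x) − b(c))ᵀ S (b(x) − b(c)).

### Age meta-variable

Priority order: (1) death-weighted mean age over single-year deaths in
[l, u]; (2) open-ended groups with life-expectancy data use the **attained
age** l + e_l (e.g. 85 + 6.5 = 91.5) — the meta-variable must be an age, and
published life tables report remaining years; (3) with no death data, the
midpoint of the interval [l, u+1) (so 65–74 → 70); (4) open-ended groups
without life expectancy use the weighted mean with u = 100.

### Vulnerability indices

Meta-variables are z-scored (ddof = 1), median-imputed if missing, and
constant columns dropped with a warning. PLS is fitted with a multivariate
response — by default the first-stage coefficient vectors **averaged over
age groups within city**, so predictors and response share the city index;
per-age stacking can be supplied as an explicit response instead. Scores
and loadings follow a deterministic sign convention (largest-magnitude
loading positive) so results are reproducible across BLAS builds. PCA is
available via `method="pca"`.

### Meta-regression

Within city *i* the age-group vectors are stacked; the marginal covariance
is blockdiag(S_ia) + J_A ⊗ Ψ with J_A the all-ones matrix over the city's
age groups — a city-level random intercept (Z_i = I₅) shared by all age
groups. Ψ is one unstructured p×p matrix common to all cities,
parameterised by its Cholesky factor with log-diagonal and optimised by
L-BFGS-B (numerical gradients, ftol 1e-12) on the REML or ML deviance; β is
profiled out by GLS at every evaluation. The start value is a
method-of-moments estimate (sample covariance of θ̂ minus the mean S,
eigenvalue-floored), with a diagonal restart if the first attempt fails.
Cities are batched by their number of age groups so the per-iteration
Cholesky factorisations run as stacked array operations.

Fixed-effect design: intercept, natural spline of the age value with a
single knot at 60 (boundary knots at the observed age range; the knot is
dropped if it falls outside that range), and the K component scores. With
K = 6 and p = 5 outcomes this gives 9 × 5 = 45 fixed-effect coefficients.

BLUPs are computed **at city level**: b̂_i = Ψ̂ Z̃ᵀ Σ_i⁻¹ (y_i − X_i β̂)
pools all of the city's age groups (the random effect is city-level, so its
BLUP must), and θ̂ᵇ_ia = θ̂ᶠ_ia + ξ̂_i with ξ̂_i = b̂_i. The reported
residual covariance is the prediction-error form Ψ̂ − Ψ̂ Z̃ᵀΣ⁻¹Z̃ Ψ̂.

AIC = −2·logL + 2·(#fixed + p(p+1)/2); when the model was fitted by REML,
the AIC is computed from an ML refit so that fixed-effect structures are
comparable. Heterogeneity: Q = Σ (θ̂ − Xβ̂)ᵀ S⁻¹ (θ̂ − Xβ̂) over the
requested subset, df = (#subset obs)·p − (#fixed) prorated by the subset's
share of observations, H = √(Q/df). Q, df and H are all reported because
the prorating convention for subset-level df is a package choice.

### Kriging

Coordinates are planar km from a local equirectangular projection about the
study centroid — adequate isotropy at country scale. Each of the p residual
dimensions is kriged independently (no co-kriging), giving a **diagonal**
covariance for ξ̂*; this ignores cross-coefficient dependence of the
extrapolation and is a documented limitation. The empirical semivariogram
is the Matheron estimator over 15 distance bins up to half the maximum
pairwise distance; the Gaussian-with-nugget model
γ(h) = nugget + psill·(1 − exp(−(h/range)²)) is fitted by least squares
weighted by pair counts, with non-negativity constraints and the range
capped at three times the largest bin distance (beyond which it is not
identifiable). Kriging is **ordinary** (weights sum to one) by default even
though BLUP residuals are mean-zero by construction — robustness to regional
mean drift; simple (zero-mean) kriging is available. A degenerate all-zero
sill falls back to mean prediction with zero variance, with a warning.

### Prediction, MMT, impacts

Predictions at unobserved cities compose the fixed part (from projected
component scores and the age spline, using the training spline's boundary
knots with linear extrapolation) and the kriged residual; covariances are
summed, valid under the independence of fixed and random effects in the
mixed model. The MMT is located by grid search over 100 points between the
1st and 99th percentile of the city's own temperatures (bounds keep the
search away from extreme tails where the curve is unstable); a flat curve
returns the midpoint with a flag. Exposure-basis boundaries at unobserved
cities use the city's own temperature range, mirroring the first-stage
convention.

Attribution is backward, same-day, through the reduced cumulative curve:
AF_t = 1 − exp(−logRR(x_t)) with the curve centred at the MMT; AN_t = AF_t
· deaths_t, summed over the period and split into cold (x < MMT) and heat
(x > MMT) days, so cold + heat + MMT-days = total exactly. Excess rates are
per 100 000 person-years with person-years = population × calendar
days/365.25. The default reference for standardisation is the study-wide
average age structure. Regional aggregation weights cities by population
(configurable).

### Uncertainty

Both Monte Carlo schemes use Cholesky/PSD-square-root normal draws with
per-location sub-seeds spawned deterministically from the master seed, so
results do not depend on iteration order. The meta-level scheme draws
β ~ N(β̂, V_β) once per iteration (shared across locations) and
ξ* ~ N(ξ̂*, V(ξ̂*)) independently per location; the uncertainty of Ψ̂
itself is not re-drawn. Kriged-residual draws are independent across
locations because per-dimension ordinary kriging does not produce their
joint posterior — a documented limitation. Default N = 1000. Aggregated
statistics must be computed per draw before taking empirical quantiles;
`eci` does exactly that and reports failed-draw counts.

## Synthetic studies

The generator emulates a national multi-city study: 87 cities on a
700 × 1000 km planar domain (five k-means regions stand in for
administrative regions), five age groups, 21 meta-variables in three
correlated blocks driven by latent vulnerability components, 30% of cities
held out, 4 years of daily data. True reduced coefficients satisfy the
second-stage model exactly: θ_ia = X_ia β_true + b_i, with X built from the
age spline of the generated demography's age-at-death values plus the
latent components, and b_i the sum of a Gaussian random field (Cholesky of a
squared-exponential covariance on planar km; sill 0.005, range 200 km) and
an independent N(0, Ψ_true) effect. Daily series invert the first-stage
model exactly: the reduced truth is expanded to full cross-basis
coefficients η = θ ⊗ c where c is the lag basis' least-squares
representation of a smooth exponentially decaying lag weight, rescaled so
the lag-cumulative reduction of η returns θ identically. Baseline daily
means come from the generated demography (city-size lognormal around
~200 000 inhabitants; age-group death rates 0.0012/0.004/0.013/0.04/0.13
per year, chosen so the youngest group has low but estimable counts);
seasonality is a ±12% winter-peaked sinusoid with small day-of-week
effects. Overdispersion (default 1.2, mild and typical of daily all-cause
mortality) uses a gamma-mixed Poisson with the gamma shape calibrated at
the series' mean count. `pop_scale` scales city sizes for low-noise limit
studies.

Not emulated: real climatology (temperature is a sinusoid plus AR(1) noise,
mean declining with latitude), calendar holidays, long-term mortality
trends, migration, or correlation between meta-variables and climate.
Passing tests therefore demonstrate statistical correctness of the pipeline
under its own assumptions, not calibration to any real population.

## Problem sizes in tests

Simulation-based checks use study sizes chosen to exercise the relevant
behaviour at reasonable cost: parameter-recovery coverage runs 200
replicates of 200 cities × 5 age groups with 2-dimensional outcome vectors
(the coverage property does not depend on p, and the batched REML makes
this the binding dimension); the holdout-validation ordering uses 20
replicates of 32-city, 2-year studies with K = 3 components; the eCI
width-ratio comparison uses 50 paired replicates of N = 1000 draws on a
constructed 50-city homogeneous region. The default 87-city study is used
once, in the acceptance script.

## Known limitations

- Per-dimension kriging ignores cross-coefficient spatial dependence.
- The H statistic's subset df prorating is a convention, not a derivation.
- The first stage excludes (rather than regularises) quasi-separated
  low-count series; very small cities with short series may drop out.
- MMT is fixed at the point estimate inside Monte Carlo impact draws; the
  eCIs do not propagate MMT-location uncertainty.
- PLS on the city-averaged response assumes effect modification is not
  strongly age-specific; an age-stacked response can be passed explicitly.
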