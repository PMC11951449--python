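"""Predictive multivariate multilevel meta-regression.

Second stage of the framework.  The reduced first-stage coefficient vectors
theta_ia (one per location x age group, each with known within-study
covariance S_ia) are pooled in the mixed model

    theta_ia = X_ia beta + b_i + eps_ia,

with X_ia built from a natural spline of the age meta-variable and the
composite vulnerability indices, b_i ~ N(0, Psi) a city-level random
intercept shared across the city's age groups, and eps_ia ~ N(0, S_ia).
Psi is an unstructured p x p matrix estimated by (restricted) maximum
likelihood with a Cholesky parameterisation; beta is profiled out by GLS.

Best linear unbiased predictions (BLUPs) of the city effects pool all of a
city's age groups; their residuals xi_i = theta^b - theta^f are the input to
the spatial extrapolation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .basis import NaturalSpline

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class MetaDesign:
    X: np.ndarray                      # n x k fixed-effect design
    cities: np.ndarray                 # n city labels
    rows: list                         # n (location, age_group) pairs
    columns: list
    age_spline: NaturalSpline = field(repr=False, default=None)
    n_components: int = 0

    @property
    def k(self):
        return self.X.shape[1]

    def row_for(self, age_value, scores):
        """Design row for a new (location, age) given its component scores."""
        scores = np.asarray(scores, dtype=float)
        if scores.size != self.n_components:
            raise ValueError(
                f"expected {self.n_components} component scores")
        age_cols = (self.age_spline([age_value])[0]
                    if self.age_spline is not None else np.empty(0))
        return np.concatenate([[1.0], age_cols, scores])


def build_design(coefs, scores=None, age_knot=60.0) -> MetaDesign:
    """Fixed-effect design: intercept, natural spline of the age value with a
    single knot (boundary at the observed age range), and the K component
    scores of each coefficient's city."""
    ages = np.array([c.age_value for c in coefs], dtype=float)
    if np.any(~np.isfinite(ages)):
        raise ValueError("every coefficient needs an age value")
    spline = None
    age_block = np.empty((len(coefs), 0))
    if np.ptp(ages) > 0:
        lo, hi = ages.min(), ages.max()
        if not lo < age_knot < hi:
            spline = NaturalSpline([], (lo, hi))
        else:
            spline = NaturalSpline([age_knot], (lo, hi))
        age_block = spline(ages)

    K = 0
    comp_block = np.empty((len(coefs), 0))
    if scores is not None and scores.shape[1] > 0:
        K = scores.shape[1]
        missing = [c.location for c in coefs if c.location not in scores.index]
        if missing:
            raise ValueError(f"missing component scores for: {sorted(set(missing))}")
        comp_block = scores.loc[[c.location for c in coefs]].to_numpy(dtype=float)

    X = np.column_stack([np.ones(len(coefs)), age_block, comp_block])
    cols = (["intercept"]
            + [f"age{j+1}" for j in range(age_block.shape[1])]
            + [f"comp{k+1}" for k in range(K)])
    return MetaDesign(X=X, cities=np.array([c.location for c in coefs]),
                      rows=[(c.location, c.age_group) for c in coefs],
                      columns=cols, age_spline=spline, n_components=K)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MetaFit:
    beta: np.ndarray                   # k x p fixed-effect matrix
    vbeta: np.ndarray                  # kp x kp covariance of vec(beta)
    psi: np.ndarray                    # p x p between-city covariance
    loglik: float                      # (restricted) log-likelihood
    method: str
    converged: bool
    design: MetaDesign = field(repr=False, default=None)
    n_obs: int = 0
    p: int = 0

    @property
    def beta_vec(self):
        return self.beta.ravel()

    @property
    def n_fixed(self):
        return self.beta.size

    @property
    def n_varpar(self):
        return self.p * (self.p + 1) // 2


@dataclass
class BlupResult:
    rows: list
    theta_fixed: np.ndarray            # n x p
    theta_blup: np.ndarray             # n x p
    xi: dict                           # city -> residual vector (p,)
    xi_cov: dict                       # city -> p x p covariance


@dataclass
class HeterogeneityStat:
    Q: float
    df: float
    H: float


class _CityGroups:
    """Per-city stacked data, batched by number of age groups for fast
    vectorised likelihood evaluations."""

    def __init__(self, coefs, design, p):
        self.p = p
        order = {}
        for i, city in enumerate(design.cities):
            order.setdefault(city, []).append(i)
        self.cities = list(order)
        by_size = {}
        for city, idx in order.items():
            by_size.setdefault(len(idx), []).append((city, idx))
        self.batches = []
        for A, members in sorted(by_size.items()):
            ys, Xs, Sb = [], [], []
            for city, idx in members:
                ys.append(np.concatenate([coefs[i].theta for i in idx]))
                Xs.append(np.kron(design.X[idx], np.eye(p)))
                blk = np.zeros((A * p, A * p))
                for a, i in enumerate(idx):
                    blk[a*p:(a+1)*p, a*p:(a+1)*p] = coefs[i].S
                Sb.append(blk)
            self.batches.append({
                "A": A,
                "cities": [m[0] for m in members],
                "idx": [m[1] for m in members],
                "y": np.asarray(ys),
                "X": np.asarray(Xs),
                "S": np.asarray(Sb),
            })
        self.n_obs = sum(len(idx) for idx in order.values())
        self.kp = design.k * p

    def sigma(self, batch, psi):
        A = batch["A"]
        return batch["S"] + np.kron(np.ones((A, A)), psi)

    def gls_pieces(self, psi, jitter=0.0):
        """Accumulate X'V^-1X, X'V^-1y, y'V^-1y and sum log|V| over cities."""
        kp = self.kp
        xtvx = np.zeros((kp, kp))
        xtvy = np.zeros(kp)
        ytvy = 0.0
        logdet = 0.0
        for batch in self.batches:
            sig = self.sigma(batch, psi)
            if jitter:
                sig = sig + jitter * np.eye(sig.shape[-1])
            cho = np.linalg.cholesky(sig)
            rhs = np.concatenate([batch["X"], batch["y"][:, :, None]], axis=2)
            w = np.linalg.solve(cho, rhs)
            xw, yw = w[:, :, :-1], w[:, :, -1]
            xtvx += np.einsum("mij,mik->jk", xw, xw)
            xtvy += np.einsum("mij,mi->j", xw, yw)
            ytvy += float(np.einsum("mi,mi->", yw, yw))
            d = np.diagonal(cho, axis1=1, axis2=2)
            logdet += 2.0 * float(np.log(d).sum())
        return xtvx, xtvy, ytvy, logdet


def _par_to_psi(par, p):
    L = np.zeros((p, p))
    tril = np.tril_indices(p)
    L[tril] = par
    d = np.arange(p)
    L[d, d] = np.exp(np.clip(L[d, d], -30, 30))
    return L @ L.T


def _psi_to_par(psi, p):
    w, v = np.linalg.eigh((psi + psi.T) / 2)
    psi = (v * np.maximum(w, 1e-8)) @ v.T
    L = np.linalg.cholesky(psi)
    d = np.arange(p)
    L[d, d] = np.log(L[d, d])
    return L[np.tril_indices(p)]


def _neg2ll(par, groups, reml):
    psi = _par_to_psi(par, groups.p)
    try:
        xtvx, xtvy, ytvy, logdet = groups.gls_pieces(psi)
    except np.linalg.LinAlgError:
        xtvx, xtvy, ytvy, logdet = groups.gls_pieces(psi, jitter=1e-8)
    sign, ld_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    n = groups.n_obs * groups.p
    val = logdet + quad + n * _LOG2PI
    if reml:
        val += ld_x - groups.kp * _LOG2PI
    return float(val)


def _mom_start(coefs, p):
    """Method-of-moments start: sample covariance of theta minus the average
    within-study covariance, floored to PSD."""
    thetas = np.asarray([c.theta for c in coefs])
    smean = np.mean([c.S for c in coefs], axis=0)
    samp = np.cov(thetas.T) if len(coefs) > 1 else np.eye(p)
    samp = np.atleast_2d(samp)
    w, v = np.linalg.eigh(samp - smean)
    psi0 = (v * np.maximum(w, 1e-4)) @ v.T
    return psi0


def fit_metareg(coefs, design: MetaDesign, method="reml") -> MetaFit:
    """Fit the multilevel multivariate meta-regression by REML or ML."""
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    p = coefs[0].theta.size
    if len({c.theta.size for c in coefs}) != 1:
        raise ValueError("all coefficient vectors must share the dimension")
    cities = {c.location for c in coefs}
    if len(cities) < 2:
        raise ValueError("need at least 2 cities")
    groups = _CityGroups(coefs, design, p)
    reml = method == "reml"

    par0 = _psi_to_par(_mom_start(coefs, p), p)
    res = minimize(_neg2ll, par0, args=(groups, reml), method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    # restart from a diagonal seed if the first attempt is shaky
    if not res.success:
        alt = minimize(_neg2ll, _psi_to_par(np.eye(p) * 1e-3, p),
                       args=(groups, reml), method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
        if alt.fun < res.fun:
            res = alt

    psi = _par_to_psi(res.x, p)
    xtvx, xtvy, _, _ = groups.gls_pieces(psi)
    beta_vec = np.linalg.solve(xtvx, xtvy)
    vbeta = np.linalg.inv(xtvx)
    return MetaFit(beta=beta_vec.reshape(design.k, p), vbeta=vbeta, psi=psi,
                   loglik=-0.5 * float(res.fun), method=method,
                   converged=bool(res.success or res.fun < 1e12),
                   design=design, n_obs=groups.n_obs, p=p)


def fixed_effects_gls(coefs, design: MetaDesign):
    """Closed-form GLS estimator with no between-city heterogeneity
    (Psi = 0): beta = (X' S^-1 X)^-1 X' S^-1 theta with S block-diagonal.
    Returns (beta matrix k x p, vbeta)."""
    p = coefs[0].theta.size
    groups = _CityGroups(coefs, design, p)
    xtvx, xtvy, _, _ = groups.gls_pieces(np.zeros((p, p)))
    beta_vec = np.linalg.solve(xtvx, xtvy)
    return beta_vec.reshape(design.k, p), np.linalg.inv(xtvx)


# ---------------------------------------------------------------------------
# BLUPs, statistics, prediction
# ---------------------------------------------------------------------------

def blup(fit: MetaFit, coefs, design: MetaDesign | None = None) -> BlupResult:
    """City-level BLUPs: the random effect of each city is predicted jointly
    from all its age groups; theta^b_ia = theta^f_ia + xi_i."""
    design = design or fit.design
    p = fit.p
    groups = _CityGroups(coefs, design, p)
    beta_vec = fit.beta_vec
    theta_f = design.X @ fit.beta
    theta_b = theta_f.copy()
    xi, xi_cov = {}, {}
    for batch in groups.batches:
        A = batch["A"]
        sig = groups.sigma(batch, fit.psi)
        Z = np.kron(np.ones((A, 1)), np.eye(p))
        resid = batch["y"] - np.einsum("mij,j->mi", batch["X"], beta_vec)
        sol = np.linalg.solve(sig, resid[:, :, None])[:, :, 0]
        M = np.linalg.solve(sig, np.broadcast_to(Z, (len(batch["cities"]),
                                                     A * p, p)).copy())
        ztsz = np.einsum("ij,mik->mjk", Z, M)
        for m, city in enumerate(batch["cities"]):
            x = fit.psi @ (Z.T @ sol[m])
            xi[city] = x
            xi_cov[city] = fit.psi - fit.psi @ ztsz[m] @ fit.psi
            for i in batch["idx"][m]:
                theta_b[i] = theta_f[i] + x
    return BlupResult(rows=design.rows, theta_fixed=theta_f,
                      theta_blup=theta_b, xi=xi, xi_cov=xi_cov)


def fit_stats(fit: MetaFit, coefs, design: MetaDesign | None = None,
              subset=None):
    """AIC (on an ML fit when the model was fitted by REML) and the
    Cochran/Higgins-Thompson heterogeneity statistics, optionally on a subset
    of row indices (fixed-effect parameters prorated by subset share)."""
    design = design or fit.design
    if subset is not None and len(subset) == 0:
        raise ValueError("empty subset")
    mlfit = fit if fit.method == "ml" else fit_metareg(coefs, design, "ml")
    aic = -2.0 * mlfit.loglik + 2.0 * (fit.n_fixed + fit.n_varpar)

    idx = range(len(coefs)) if subset is None else subset
    resid = [coefs[i].theta - fit.beta.T @ design.X[i] for i in idx]
    q = float(sum(r @ np.linalg.solve(coefs[i].S, r)
                  for i, r in zip(idx, resid)))
    n_sub = len(list(idx))
    df = n_sub * fit.p - fit.n_fixed * n_sub / len(coefs)
    h = float(np.sqrt(max(q, 0.0) / df)) if df > 0 else np.nan
    return aic, HeterogeneityStat(Q=q, df=df, H=h)


def predict_fixed(fit: MetaFit, X_new):
    """Fixed-effect predictions theta^f* = X* beta with per-row covariance
    (x' kron I_p) V_beta (x kron I_p)'."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != fit.beta.shape[0]:
        raise ValueError(f"design rows must have {fit.beta.shape[0]} columns")
    theta = X_new @ fit.beta
    covs = []
    eye = np.eye(fit.p)
    for x in X_new:
        kr = np.kron(x[None, :], eye)
        covs.append(kr @ fit.vbeta @ kr.T)
    return theta, np.asarray(covs)
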