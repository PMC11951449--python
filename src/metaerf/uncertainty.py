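"""Monte Carlo empirical confidence intervals for impact measures.

Two simulation schemes are provided.  The prediction-level (legacy) scheme
draws each location's coefficients independently from its predicted
distribution, which ignores the correlation induced by the shared
fixed-effect estimates and under-states the uncertainty of aggregated
impacts.  The meta-level scheme draws the fixed-effect coefficients once per
iteration (shared by every location) plus independent draws of the kriged
residuals, propagating the correlation into any aggregation computed per
draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import warnings


@dataclass
class SimEnsemble:
    """N coefficient draws per (location, age group)."""

    draws: np.ndarray                  # N x n_rows x p
    rows: list                         # (location, age_group) per row
    scheme: str
    seed: int = 0

    @property
    def n_draws(self):
        return self.draws.shape[0]

    def row_index(self, location, age_group):
        return self.rows.index((location, age_group))

    def to_frame(self):
        """Long-format table (draw, location, age_group, theta_1..p)."""
        import pandas as pd
        N, n, p = self.draws.shape
        df = pd.DataFrame({
            "draw": np.repeat(np.arange(N), n),
            "location": [r[0] for r in self.rows] * N,
            "age_group": [r[1] for r in self.rows] * N,
        })
        flat = self.draws.reshape(N * n, p)
        for j in range(p):
            df[f"theta_{j+1}"] = flat[:, j]
        return df


def _safe_cholesky(cov, label=""):
    """Cholesky factor, falling back to an exact PSD square root for
    singular matrices; genuinely indefinite input is repaired with a
    warning by clipping negative eigenvalues."""
    cov = np.asarray(cov, dtype=float)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((cov + cov.T) / 2)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            warnings.warn(f"non-PSD covariance{label}: nearest-PSD repair "
                          "applied", RuntimeWarning, stacklevel=3)
        return v * np.sqrt(np.maximum(w, 0.0))


def simulate_meta_level(fit, preds, kriged, N=1000, seed=0) -> SimEnsemble:
    """Meta-level scheme: per draw, one beta ~ N(beta_hat, V_beta) shared by
    all locations, composed with independent residual draws
    xi* ~ N(xi_hat*, V(xi*)) per location.

    ``preds`` are PredictedERF objects carrying their design row ``x_row``;
    ``kriged`` maps location -> KrigedResidual.
    """
    p = fit.p
    rows = [(pr.location, pr.age_group) for pr in preds]
    chol_b = _safe_cholesky(fit.vbeta, " of beta")
    master = np.random.SeedSequence(seed)
    beta_rng = np.random.default_rng(master.spawn(1)[0])
    beta_draws = fit.beta_vec + (chol_b @ beta_rng.standard_normal(
        (fit.beta_vec.size, N))).T                      # N x kp

    locs = sorted({pr.location for pr in preds})
    xi_draws = {}
    for loc, ss in zip(locs, np.random.SeedSequence((seed, 1)).spawn(len(locs))):
        kr = kriged[loc]
        rng = np.random.default_rng(ss)
        sd = np.sqrt(np.maximum(np.asarray(kr.var, dtype=float), 0.0))
        xi_draws[loc] = kr.xi + rng.standard_normal((N, p)) * sd

    draws = np.empty((N, len(preds), p))
    eye = np.eye(p)
    for j, pr in enumerate(preds):
        kr_x = np.kron(pr.x_row[None, :], eye)          # p x kp
        draws[:, j, :] = beta_draws @ kr_x.T + xi_draws[pr.location]
    return SimEnsemble(draws=draws, rows=rows, scheme="meta", seed=seed)


def simulate_pred_level(preds, N=1000, seed=0) -> SimEnsemble:
    """Prediction-level (legacy) scheme: independent multivariate normal
    draws per (location, age group) from N(theta*, V(theta*))."""
    rows = [(pr.location, pr.age_group) for pr in preds]
    p = np.asarray(preds[0].theta).size
    draws = np.empty((N, len(preds), p))
    seqs = np.random.SeedSequence((seed, 2)).spawn(len(preds))
    for j, (pr, ss) in enumerate(zip(preds, seqs)):
        rng = np.random.default_rng(ss)
        chol = _safe_cholesky(pr.cov, f" at {pr.location}/{pr.age_group}")
        draws[:, j, :] = pr.theta + rng.standard_normal((N, p)) @ chol.T
    return SimEnsemble(draws=draws, rows=rows, scheme="prediction", seed=seed)


def eci(ensemble: SimEnsemble, statistic, level=0.95, point=None):
    """Empirical confidence interval of a statistic of the coefficient draws.

    ``statistic`` maps one draw (n_rows x p array) to a scalar (or array);
    failed draws are dropped and counted.  Returns (point, lo, hi, n_failed)
    where the point estimate is the statistic of ``point`` draws when given,
    otherwise the median of the simulated values.
    """
    if ensemble.n_draws < 100:
        raise ValueError("need at least 100 draws")
    vals, n_failed = [], 0
    for d in ensemble.draws:
        try:
            vals.append(statistic(d))
        except Exception:
            n_failed += 1
    vals = np.asarray(vals, dtype=float)
    alpha = (1.0 - level) / 2
    lo = np.quantile(vals, alpha, axis=0)
    hi = np.quantile(vals, 1 - alpha, axis=0)
    pt = statistic(point) if point is not None else np.median(vals, axis=0)
    return pt, lo, hi, n_failed
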