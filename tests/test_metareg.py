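"""Multivariate multilevel meta-regression: REML, BLUPs, statistics."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from metaerf.basis import ReducedCoef
from metaerf.metareg import (MetaDesign, blup, build_design, fit_metareg,
                             fit_stats, fixed_effects_gls, predict_fixed)


def _scalar_dataset(rng, n=40, psi=1.2, mu=-0.5, s_lo=0.1, s_hi=0.3):
    S = rng.uniform(s_lo, s_hi, n)
    y = mu + rng.normal(0, np.sqrt(psi + S))
    coefs = [ReducedCoef(f"c{i}", "all", [y[i]], [[S[i]]]) for i in range(n)]
    design = MetaDesign(X=np.ones((n, 1)),
                        cities=np.array([f"c{i}" for i in range(n)]),
                        rows=[(f"c{i}", "all") for i in range(n)],
                        columns=["intercept"])
    return coefs, design, y, S


def _scalar_reml_oracle(y, S, n):
    """Independent 1-D REML: profile likelihood optimised by bounded search."""
    def neg2llr(psi):
        w = 1 / (psi + S)
        mu = np.sum(w * y) / np.sum(w)
        return (np.sum(np.log(psi + S)) + np.sum(w * (y - mu) ** 2)
                + np.log(np.sum(w)) + (n - 1) * np.log(2 * np.pi))
    res = minimize_scalar(neg2llr, bounds=(1e-10, 50), method="bounded",
                          options={"xatol": 1e-13})
    w = 1 / (res.x + S)
    return res.x, np.sum(w * y) / np.sum(w)


class TestFit:
    def test_scalar_reml_matches_independent_oracle(self, rng):
        coefs, design, y, S = _scalar_dataset(rng)
        psi_o, mu_o = _scalar_reml_oracle(y, S, len(y))
        fit = fit_metareg(coefs, design, "reml")
        assert abs(fit.psi[0, 0] - psi_o) < 1e-6
        assert abs(fit.beta[0, 0] - mu_o) < 1e-6

    def test_zero_psi_limit_equals_closed_form_gls(self, rng):
        coefs, design, y, S = _scalar_dataset(rng)
        beta, vbeta = fixed_effects_gls(coefs, design)
        w = 1 / S
        np.testing.assert_allclose(beta[0, 0], np.sum(w * y) / np.sum(w),
                                   atol=1e-10)
        np.testing.assert_allclose(vbeta[0, 0], 1 / np.sum(w), atol=1e-12)

    def test_multivariate_parameter_recovery_coverage(self):
        """95% CIs for the fixed effects cover the truth near nominal rate."""
        p, k, ngr, ncity = 2, 2, 3, 80
        beta_true = np.array([[0.3, -0.2], [0.1, 0.25]])
        chp = np.linalg.cholesky(np.array([[0.03, 0.008], [0.008, 0.02]]))
        hits = []
        for rep in range(25):
            r = np.random.default_rng(500 + rep)
            coefs, Xr, cities = [], [], []
            for i in range(ncity):
                b = chp @ r.standard_normal(p)
                for a in range(ngr):
                    x = np.array([1.0, r.normal()])
                    Ssc = np.diag(r.uniform(0.005, 0.03, p))
                    th = x @ beta_true + b \
                        + np.sqrt(np.diag(Ssc)) * r.standard_normal(p)
                    coefs.append(ReducedCoef(f"c{i}", a, th, Ssc))
                    Xr.append(x)
                    cities.append(f"c{i}")
            design = MetaDesign(X=np.array(Xr), cities=np.array(cities),
                                rows=[(c.location, c.age_group)
                                      for c in coefs], columns=["i", "x"])
            fit = fit_metareg(coefs, design, "reml")
            se = np.sqrt(np.diag(fit.vbeta)).reshape(k, p)
            hits.append((np.abs(fit.beta - beta_true) < 1.96 * se).mean())
        assert 0.88 <= np.mean(hits) <= 1.0

    def test_reml_optimum_is_local_minimum(self, rng):
        from metaerf.metareg import _CityGroups, _neg2ll, _psi_to_par
        coefs, design, *_ = _scalar_dataset(rng)
        fit = fit_metareg(coefs, design, "reml")
        groups = _CityGroups(coefs, design, 1)
        par = _psi_to_par(fit.psi, 1)
        f0 = _neg2ll(par, groups, True)
        for d in (-0.05, 0.05):
            assert _neg2ll(par + d, groups, True) >= f0 - 1e-9


class TestDesign:
    def _coefs(self, rng, ncity=10, ngr=5, p=5):
        coefs = []
        ages = [30.0, 55.0, 70.0, 80.0, 91.0]
        for i in range(ncity):
            for a in range(ngr):
                c = ReducedCoef(f"c{i}", a, rng.normal(size=p), np.eye(p))
                c.age_value = ages[a] + rng.normal(0, 1)
                coefs.append(c)
        return coefs

    def test_k6_gives_9_columns_and_45_fixed_coefficients(self, rng):
        import pandas as pd
        coefs = self._coefs(rng)
        scores = pd.DataFrame(rng.normal(size=(10, 6)),
                              index=[f"c{i}" for i in range(10)],
                              columns=[f"comp{k}" for k in range(1, 7)])
        design = build_design(coefs, scores)
        assert design.X.shape[1] == 9
        fit = fit_metareg(coefs, design, "ml")
        assert fit.beta.size == 45

    def test_constant_age_no_scores_collapses_to_intercept(self, rng):
        coefs = self._coefs(rng, ngr=1)
        for c in coefs:
            c.age_value = 70.0
        design = build_design(coefs, None)
        assert design.columns == ["intercept"]

    def test_single_interior_knot_spans_two_columns(self, rng):
        coefs = self._coefs(rng)
        design = build_design(coefs, None)
        assert design.X.shape[1] == 3  # intercept + 2 age-spline columns

    def test_missing_scores_rejected(self, rng):
        import pandas as pd
        coefs = self._coefs(rng)
        scores = pd.DataFrame(rng.normal(size=(9, 2)),
                              index=[f"c{i}" for i in range(9)])
        with pytest.raises(ValueError, match="c9"):
            build_design(coefs, scores)


class TestBlup:
    def test_scalar_shrinkage_weight(self, rng):
        coefs, design, y, S = _scalar_dataset(rng)
        fit = fit_metareg(coefs, design, "reml")
        res = blup(fit, coefs, design)
        i = 5
        lam = fit.psi[0, 0] / (fit.psi[0, 0] + S[i])
        expected = fit.beta[0, 0] + lam * (y[i] - fit.beta[0, 0])
        assert res.theta_blup[i, 0] == pytest.approx(expected, abs=1e-8)
        # convex combination of first-stage and fixed prediction
        lo, hi = sorted([y[i], fit.beta[0, 0]])
        assert lo - 1e-9 <= res.theta_blup[i, 0] <= hi + 1e-9

    def test_zero_psi_means_no_random_effect(self, rng):
        coefs, design, y, S = _scalar_dataset(rng, psi=0.0, s_lo=1.0,
                                              s_hi=2.0)
        fit = fit_metareg(coefs, design, "reml")
        if fit.psi[0, 0] < 1e-6:  # boundary solution expected
            res = blup(fit, coefs, design)
            np.testing.assert_allclose(res.theta_blup, res.theta_fixed,
                                       atol=1e-4)

    def test_vanishing_s_gives_no_shrinkage(self, rng):
        coefs, design, y, S = _scalar_dataset(rng)
        coefs[0].S = np.array([[1e-10]])
        fit = fit_metareg(coefs, design, "reml")
        res = blup(fit, coefs, design)
        assert res.theta_blup[0, 0] == pytest.approx(coefs[0].theta[0],
                                                     abs=1e-6)

    def test_blup_equals_fixed_plus_shared_city_residual(self, rng):
        p, ncity, ngr = 3, 12, 4
        coefs, Xr, cities = [], [], []
        for i in range(ncity):
            for a in range(ngr):
                coefs.append(ReducedCoef(f"c{i}", a,
                                         rng.normal(size=p),
                                         np.eye(p) * rng.uniform(0.05, 0.2)))
                Xr.append([1.0])
                cities.append(f"c{i}")
        design = MetaDesign(X=np.array(Xr), cities=np.array(cities),
                            rows=[(c.location, c.age_group) for c in coefs],
                            columns=["intercept"])
        fit = fit_metareg(coefs, design, "reml")
        res = blup(fit, coefs, design)
        for j, (city, _) in enumerate(res.rows):
            np.testing.assert_allclose(
                res.theta_blup[j] - res.theta_fixed[j], res.xi[city],
                atol=1e-10)


class TestStats:
    def test_q_chi2_under_homogeneity(self):
        """With no heterogeneity Q follows a chi-square with df dof."""
        from scipy.stats import chi2
        inside = 0
        n = 30
        for rep in range(40):
            r = np.random.default_rng(900 + rep)
            S = r.uniform(0.5, 1.5, n)
            y = 2.0 + r.normal(0, np.sqrt(S))
            coefs = [ReducedCoef(f"c{i}", "all", [y[i]], [[S[i]]])
                     for i in range(n)]
            design = MetaDesign(X=np.ones((n, 1)),
                                cities=np.array([f"c{i}" for i in range(n)]),
                                rows=[(f"c{i}", "all") for i in range(n)],
                                columns=["intercept"])
            fit = fit_metareg(coefs, design, "reml")
            _, het = fit_stats(fit, coefs, design)
            lo, hi = chi2.ppf([0.005, 0.995], het.df)
            inside += int(lo <= het.Q <= hi)
        assert inside >= 34

    def test_h_is_sqrt_q_over_df(self, rng):
        coefs, design, *_ = _scalar_dataset(rng)
        fit = fit_metareg(coefs, design, "reml")
        _, het = fit_stats(fit, coefs, design)
        assert het.H == pytest.approx(np.sqrt(het.Q / het.df))

    def test_adding_column_never_increases_ml_deviance(self, rng):
        coefs, design, y, S = _scalar_dataset(rng)
        fit1 = fit_metareg(coefs, design, "ml")
        x2 = np.column_stack([design.X, rng.normal(size=len(y))])
        design2 = MetaDesign(X=x2, cities=design.cities, rows=design.rows,
                             columns=["intercept", "noise"])
        fit2 = fit_metareg(coefs, design2, "ml")
        assert fit2.loglik >= fit1.loglik - 1e-6

    def test_empty_subset_rejected(self, rng):
        coefs, design, *_ = _scalar_dataset(rng)
        fit = fit_metareg(coefs, design, "reml")
        with pytest.raises(ValueError):
            fit_stats(fit, coefs, design, subset=[])


class TestPredictFixed:
    def test_training_row_reproduced(self, rng):
        coefs, design, *_ = _scalar_dataset(rng)
        fit = fit_metareg(coefs, design, "reml")
        res = blup(fit, coefs, design)
        theta, _ = predict_fixed(fit, design.X[:3])
        np.testing.assert_allclose(theta, res.theta_fixed[:3], atol=1e-12)

    def test_duplicated_row_identical(self, rng):
        coefs, design, *_ = _scalar_dataset(rng)
        fit = fit_metareg(coefs, design, "reml")
        theta, cov = predict_fixed(fit, [[1.0], [1.0]])
        np.testing.assert_array_equal(theta[0], theta[1])
        np.testing.assert_array_equal(cov[0], cov[1])

    def test_covariance_matches_monte_carlo(self, rng):
        p, k = 3, 2
        ncity, ngr = 25, 3
        coefs, Xr, cities = [], [], []
        for i in range(ncity):
            for a in range(ngr):
                coefs.append(ReducedCoef(f"c{i}", a, rng.normal(size=p),
                                         np.eye(p) * 0.05))
                Xr.append([1.0, rng.normal()])
                cities.append(f"c{i}")
        design = MetaDesign(X=np.array(Xr), cities=np.array(cities),
                            rows=[(c.location, c.age_group) for c in coefs],
                            columns=["i", "x"])
        fit = fit_metareg(coefs, design, "reml")
        x_new = np.array([1.0, 0.7])
        _, cov = predict_fixed(fit, x_new)
        draws = rng.multivariate_normal(fit.beta_vec, fit.vbeta, size=20000)
        eye = np.eye(p)
        kr = np.kron(x_new[None, :], eye)
        mc = np.cov((draws @ kr.T).T)
        # absolute floor covers MC noise on near-zero off-diagonal entries
        np.testing.assert_allclose(cov[0], mc, rtol=0.05, atol=3e-4)

    def test_column_mismatch_rejected(self, rng):
        coefs, design, *_ = _scalar_dataset(rng)
        fit = fit_metareg(coefs, design, "reml")
        with pytest.raises(ValueError):
            predict_fixed(fit, [[1.0, 2.0]])


class TestModelSelection:
    def test_aic_scan_selects_near_true_component_count(self):
        """With three informative vulnerability components, the AIC scan over
        K = 0..8 places its minimum at or above three components."""
        import pandas as pd
        from metaerf.synthetic import StudyConfig, gen_study
        from metaerf.vulnerability import fit_components
        from metaerf.metareg import build_design, fit_stats

        study = gen_study(StudyConfig(n_locations=50, seed=606,
                                      spatial_sill=0.0), with_series=False)
        rng = np.random.default_rng(0)
        coefs = []
        for i, ((loc, age), row) in enumerate(
                study.truth["theta"].iterrows()):
            S = np.eye(5) * 0.003
            theta = row.to_numpy() + rng.multivariate_normal(np.zeros(5), S)
            c = ReducedCoef(loc, age, theta, S)
            c.age_value = study.truth["age_value"][(loc, age)]
            coefs.append(c)
        resp = pd.DataFrame(
            study.truth["theta"].groupby("location").mean(),
            index=study.metavars.index)
        aics = []
        for K in range(9):
            scores = None
            if K > 0:
                comp = fit_components(study.metavars, resp, K=K)
                scores = comp.training_scores
            design = build_design(coefs, scores)
            fit = fit_metareg(coefs, design, "ml")
            aic, _ = fit_stats(fit, coefs, design)
            aics.append(aic)
        best = int(np.argmin(aics))
        assert best >= 3
        assert aics[3] < aics[0]
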