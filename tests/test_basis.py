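"""Spline bases, cross-basis construction, reduction and ERF curves."""

import numpy as np
import pytest

from metaerf.basis import (CrossBasisSpec, ReducedCoef, build_crossbasis,
                           erf_curve, log_lag_knots, reduce_coefs,
                           reduction_matrix, spline_basis)


def cox_de_boor(x, t, j, k):
    """Textbook B-spline recursion, independent of the implementation."""
    if k == 0:
        # right-closed on the last interval so the basis sums to one
        last = t[j + 1] == t[-1]
        return np.where((t[j] <= x) & ((x < t[j + 1]) | (last & (x <= t[j + 1]))),
                        1.0, 0.0)
    out = np.zeros_like(np.asarray(x, dtype=float))
    if t[j + k] > t[j]:
        out += (x - t[j]) / (t[j + k] - t[j]) * cox_de_boor(x, t, j, k - 1)
    if t[j + k + 1] > t[j + 1]:
        out += (t[j + k + 1] - x) / (t[j + k + 1] - t[j + 1]) \
            * cox_de_boor(x, t, j + 1, k - 1)
    return out


class TestSplineBasis:
    def test_bspline_dimension_degree2_three_knots(self):
        x = np.linspace(0, 30, 200)
        b = spline_basis(x, "bspline", 2, [5.0, 20.0, 25.0], (0.0, 30.0))
        assert b.shape[1] == 5

    def test_bspline_matches_cox_de_boor_recursion(self):
        degree, knots, boundary = 2, [5.0, 20.0, 25.0], (0.0, 30.0)
        probes = np.linspace(0.3, 29.7, 20)
        b = spline_basis(probes, "bspline", degree, knots, boundary)
        t = np.r_[[boundary[0]] * (degree + 1), knots,
                  [boundary[1]] * (degree + 1)]
        full = np.column_stack([cox_de_boor(probes, t, j, degree)
                                for j in range(len(t) - degree - 1)])
        np.testing.assert_allclose(b, full[:, 1:], atol=1e-10)

    def test_natural_spline_zero_second_derivative_at_boundary(self):
        ns = lambda v: spline_basis(v, "natural", interior_knots=[12.0],
                                    boundary=(2.0, 28.0))
        h = 1e-4
        for bound in (2.0, 28.0):
            d2 = (ns([bound + h]) - 2 * ns([bound]) + ns([bound - h])) / h**2
            assert np.abs(d2).max() < 1e-4

    def test_natural_spline_linear_beyond_boundary(self):
        ns = lambda v: spline_basis(np.asarray(v), "natural",
                                    interior_knots=[12.0], boundary=(2.0, 28.0))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = ns([30.0, 31.0, 32.0])
        np.testing.assert_allclose(v[2] - v[1], v[1] - v[0], atol=1e-10)

    def test_boundary_must_enclose_knots(self):
        with pytest.raises(ValueError):
            spline_basis(np.linspace(0, 1, 10), "bspline", 2, [2.0], (0.0, 1.0))


class TestLogLagKnots:
    def test_closed_form_21_3(self):
        np.testing.assert_allclose(log_lag_knots(21, 3),
                                   np.exp(np.arange(1, 4) / 4 * np.log(21)))
        np.testing.assert_allclose(log_lag_knots(21, 3),
                                   [2.1407, 4.5826, 9.8099], atol=1e-4)

    def test_single_knot_is_log_midpoint(self):
        np.testing.assert_allclose(log_lag_knots(21, 1), np.sqrt(21))

    def test_knots_strictly_inside(self):
        k = log_lag_knots(21, 3)
        assert np.all(k > 1) and np.all(k < 21)
        assert np.all(np.diff(k) > 0)

    def test_too_many_knots_rejected(self):
        with pytest.raises(ValueError):
            log_lag_knots(5, 5)


class TestCrossBasis:
    def test_constant_series_gives_constant_columns(self, resolved_spec):
        spec, x = resolved_spec
        const = np.full(100, 15.0)
        cb = build_crossbasis(const, spec)
        body = cb[spec.max_lag:]
        assert np.allclose(body, body[0], atol=1e-12)
        assert np.isnan(cb[:spec.max_lag]).all()

    def test_single_lag_column_is_moving_sum(self, rng):
        # max_lag=1 collapses the lag basis to a single all-ones column
        spec = CrossBasisSpec(max_lag=1).resolve(rng.normal(18, 6, 60))
        x = rng.normal(18, 6, 60)
        cb = build_crossbasis(x, spec)
        e = spec.exposure_basis(x)
        expected = e[1:] + e[:-1]
        np.testing.assert_allclose(cb[1:], expected, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(20, 5, 30)
        spec = CrossBasisSpec(max_lag=6, n_lag_knots=2).resolve(x)
        cb = build_crossbasis(x, spec)
        e = spec.exposure_basis(x)
        lagb = spec.lag_basis()
        T, p, q = len(x), e.shape[1], lagb.shape[1]
        oracle = np.full((T, p * q), np.nan)
        for t in range(spec.max_lag, T):
            for j in range(p):
                for k in range(q):
                    oracle[t, j * q + k] = sum(
                        e[t - lag, j] * lagb[lag, k]
                        for lag in range(spec.max_lag + 1))
        np.testing.assert_allclose(cb[spec.max_lag:], oracle[spec.max_lag:],
                                   atol=1e-12)


class TestReduction:
    def test_reduced_dimension_is_five(self, resolved_spec):
        spec, _ = resolved_spec
        pq = spec.n_exposure * spec.n_lag
        rc = reduce_coefs(np.zeros(pq), np.zeros((pq, pq)), spec)
        assert rc.theta.shape == (5,)
        np.testing.assert_array_equal(rc.theta, 0)
        np.testing.assert_array_equal(rc.S, 0)

    def test_linearity(self, resolved_spec, rng):
        spec, _ = resolved_spec
        pq = spec.n_exposure * spec.n_lag
        v = np.zeros((pq, pq))
        e1, e2 = rng.normal(size=pq), rng.normal(size=pq)
        a = 3.7
        r = reduce_coefs(a * e1 + e2, v, spec).theta
        np.testing.assert_allclose(
            r, a * reduce_coefs(e1, v, spec).theta
            + reduce_coefs(e2, v, spec).theta, atol=1e-10)

    def test_reduction_equals_lag_summed_surface(self, resolved_spec, rng):
        spec, x = resolved_spec
        eta = rng.normal(size=spec.n_exposure * spec.n_lag)
        rc = reduce_coefs(eta, np.eye(eta.size), spec)
        probes = np.percentile(x, [2, 10, 30, 45, 55, 70, 80, 90, 95, 99])
        b = spec.exposure_basis(probes)
        lagb = spec.lag_basis()
        em = eta.reshape(spec.n_exposure, spec.n_lag)
        surface = sum(b @ (em @ lagb[lag]) for lag in range(spec.max_lag + 1))
        np.testing.assert_allclose(b @ rc.theta, surface, atol=1e-10)

    def test_dimension_mismatch_rejected(self, resolved_spec):
        spec, _ = resolved_spec
        with pytest.raises(ValueError, match="25"):
            reduce_coefs(np.zeros(7), np.zeros((7, 7)), spec)


class TestErfCurve:
    def test_zero_theta_gives_flat_curve(self, resolved_spec):
        spec, x = resolved_spec
        rc = ReducedCoef("a", "b", np.zeros(5), np.zeros((5, 5)))
        curve = erf_curve(rc, spec, np.percentile(x, [5, 50, 95]), 20.0)
        assert np.all(curve["logrr"] == 0)
        assert np.all(curve["hi"] - curve["lo"] == 0)

    def test_zero_at_center(self, resolved_spec, rng):
        spec, x = resolved_spec
        rc = ReducedCoef("a", "b", rng.normal(size=5), np.zeros((5, 5)))
        center = float(np.percentile(x, 60))
        curve = erf_curve(rc, spec, np.array([center, 10.0, 25.0]), center)
        assert curve["logrr"].iloc[0] == 0.0

    def test_se_matches_monte_carlo(self, resolved_spec, rng):
        spec, x = resolved_spec
        theta = rng.normal(0, 0.3, 5)
        a = rng.normal(size=(5, 5))
        S = a @ a.T * 0.01
        rc = ReducedCoef("a", "b", theta, S)
        grid = np.percentile(x, [2, 25, 50, 75, 98])
        center = float(np.percentile(x, 60))
        curve = erf_curve(rc, spec, grid, center)
        draws = rng.multivariate_normal(theta, S, size=20000)
        b = spec.exposure_basis(grid) - spec.exposure_basis([center])
        mc_se = (b @ draws.T).std(axis=1)
        np.testing.assert_allclose(curve["se"], mc_se, rtol=0.02)


def test_lag0_crossbasis_equals_exposure_basis(rng):
    """With a single lag-0 column the cross-basis is the plain exposure basis."""
    x = rng.normal(18, 6, 80)
    spec = CrossBasisSpec(max_lag=1).resolve(x)
    m = reduction_matrix(spec)
    # reduction of the max_lag=1 basis sums two identical lag weights
    np.testing.assert_allclose(m, 2 * np.eye(5), atol=1e-12)
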