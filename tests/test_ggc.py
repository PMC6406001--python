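"""Granger-Geweke core: AR/VAR fits, feedback measure, lag selection, matrices.

Expected values come from independent oracles: processes simulated from known
coefficients, and population feedback from the closed-form Yule-Walker
autocovariance solution.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowgc import ggc
from flowgc.errors import DegenerateInputError, FlowgcError, InsufficientDataError
from flowgc.synthetic import var_autocovariance, population_pairwise_f

from conftest import make_panel


def _simulate_var1(A, T, seed, burn=500):
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    x = np.zeros((T + burn, n))
    e = rng.normal(size=(T + burn, n))
    for t in range(1, T + burn):
        x[t] = A @ x[t - 1] + e[t]
    return x[burn:]


class TestRestrictedFit:
    def test_white_noise_recovers_sample_variance(self, rng):
        y = rng.normal(size=5000)
        fit = ggc.fit_ar_restricted(y, lag=1)
        assert fit.residual_variance == pytest.approx(y.var(), rel=0.05)
        assert abs(fit.coefficients[0]) < 0.05

    def test_ar1_coefficient_and_innovation_variance(self):
        y = _simulate_var1(np.array([[0.9]]), 100_000, seed=10)[:, 0]
        fit = ggc.fit_ar_restricted(y, lag=1)
        assert fit.coefficients[0] == pytest.approx(0.9, abs=0.01)
        assert fit.residual_variance == pytest.approx(1.0, abs=0.02)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ggc.fit_ar_restricted(np.ones(200), lag=1)

    def test_lag_exceeding_segment_insufficient(self, rng):
        with pytest.raises(InsufficientDataError):
            ggc.fit_ar_restricted(rng.normal(size=10), lag=8)

    def test_run_boundary_rows_dropped(self, rng):
        y = rng.normal(size=200)
        fit = ggc.fit_ar_restricted(y, lag=3, run_boundaries=(0, 100))
        assert fit.n_effective == 200 - 2 * 3


class TestFullFit:
    def test_independent_series_near_zero_cross_terms(self, rng):
        x = rng.normal(size=50_000)
        y = rng.normal(size=50_000)
        fit = ggc.fit_var_full(x, y, lag=1)
        a_b = fit.coef_x     # (a_1, b_1)
        c_d = fit.coef_y     # (c_1, d_1)
        assert abs(a_b[1]) < 0.02 and abs(c_d[0]) < 0.02
        assert abs(fit.residual_covariance) < 0.02

    def test_recovers_planted_cross_coefficient(self):
        data = _simulate_var1(np.array([[0.0, 0.0], [0.5, 0.0]]), 100_000, seed=11)
        fit = ggc.fit_var_full(data[:, 0], data[:, 1], lag=1)
        assert fit.coef_y[0] == pytest.approx(0.5, abs=0.01)

    def test_identical_series_degenerate(self, rng):
        x = rng.normal(size=500)
        with pytest.raises(DegenerateInputError):
            ggc.fit_var_full(x, x, lag=1)


class TestGewekeF:
    def test_matches_population_oracle(self):
        A = np.array([[0.6, 0.0], [0.4, 0.5]])
        data = _simulate_var1(A, 50_000, seed=12)
        f_xy, f_yx = ggc.geweke_f(data[:, 0], data[:, 1], lag=1)
        gam = var_autocovariance([A], np.eye(2), 3)
        assert f_xy == pytest.approx(population_pairwise_f(gam, 0, 1, 1), abs=0.02)
        assert f_yx == pytest.approx(population_pairwise_f(gam, 1, 0, 1), abs=0.005)
        assert f_yx < 0.005     # no feedback planted in this direction

    def test_nonnegative_by_construction(self, rng):
        x = rng.normal(size=800)
        y = rng.normal(size=800)
        f_xy, f_yx = ggc.geweke_f(x, y, lag=4)
        assert f_xy >= 0 and f_yx >= 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale_x=st.floats(0.1, 50), shift_x=st.floats(-100, 100),
        scale_y=st.floats(0.1, 50), shift_y=st.floats(-100, 100),
    )
    def test_affine_invariance(self, scale_x, shift_x, scale_y, shift_y):
        rng = np.random.default_rng(77)
        data = _simulate_var1(np.array([[0.5, 0.0], [0.3, 0.4]]), 1500, seed=13)
        x, y = data[:, 0], data[:, 1]
        f0 = ggc.geweke_f(x, y, lag=2)
        f1 = ggc.geweke_f(scale_x * x + shift_x, scale_y * y + shift_y, lag=2)
        np.testing.assert_allclose(f0, f1, atol=1e-8)


class TestLrPvalue:
    def test_null_statistic_gives_one(self):
        assert ggc.lr_pvalue(0.0, 1000, 1) == 1.0

    def test_negative_f_clipped_to_one(self):
        assert ggc.lr_pvalue(-0.3, 1000, 2) == 1.0

    def test_far_tail(self):
        assert ggc.lr_pvalue(50 / 1000, 1000, 1) < 1e-10

    def test_monotone_in_f(self):
        ps = [ggc.lr_pvalue(f, 500, 3) for f in (0.0, 0.01, 0.05, 0.2)]
        assert ps == sorted(ps, reverse=True)


class TestLagSelection:
    def test_single_candidate(self, rng):
        assert ggc.select_lag_aic(rng.normal(size=300), rng.normal(size=300),
                                  lag_max=1) == 1

    def test_planted_lag3_recovered(self):
        rng = np.random.default_rng(42)
        T = 1200
        e = rng.normal(size=(T + 50, 2))
        x = np.zeros(T + 50)
        y = np.zeros(T + 50)
        for t in range(3, T + 50):
            x[t] = 0.3 * x[t - 1] + e[t, 0]
            y[t] = 0.3 * y[t - 1] + 0.4 * x[t - 3] + e[t, 1]
        assert ggc.select_lag_aic(x[50:], y[50:], lag_max=10) == 3

    def test_null_concentrates_at_one(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(500 + s)
            hits += ggc.select_lag_aic(rng.normal(size=1200),
                                       rng.normal(size=1200), lag_max=10) == 1
        assert hits >= 12      # penalty dominates under independence


class TestFlowMatrix:
    def test_two_node_panel_reduces_to_pair(self, rng):
        data = _simulate_var1(np.array([[0.5, 0.0], [0.3, 0.4]]), 1000, seed=14)
        panel = make_panel(data, "two")
        fm = ggc.compute_flow_matrix(panel, lag_max=4)
        l = ggc.select_lag_aic(data[:, 0], data[:, 1], lag_max=4)
        f01, f10 = ggc.geweke_f(data[:, 0], data[:, 1], lag=l)
        assert fm.lag[0, 1] == l
        assert fm.f[0, 1] == pytest.approx(max(f01, 0.0), abs=1e-12)
        assert fm.f[1, 0] == pytest.approx(max(f10, 0.0), abs=1e-12)
        assert fm.f[0, 0] == 0.0 and fm.p[0, 0] == 1.0

    def test_batched_equals_pairwise_reference(self, small_panels):
        panels, _ = small_panels
        panel = panels["sub0000"]
        fm = ggc.compute_flow_matrix(panel, lag_max=5)
        data = ggc.demean_per_run(panel.data, panel.run_boundaries)
        ref = ggc._compute_flow_loop(panel, data, lag_max=5)
        np.testing.assert_allclose(fm.f, ref.f, atol=1e-10)
        np.testing.assert_array_equal(fm.lag, ref.lag)

    def test_node_permutation_equivariance(self, rng):
        data = _simulate_var1(
            np.array([[0.4, 0, 0], [0.3, 0.4, 0], [0, 0.25, 0.4]]), 900, seed=15)
        perm = np.array([2, 0, 1])
        fm = ggc.compute_flow_matrix(make_panel(data, "a"), lag_max=3)
        fm_p = ggc.compute_flow_matrix(make_panel(data[:, perm], "b"), lag_max=3)
        np.testing.assert_allclose(fm_p.f, fm.f[np.ix_(perm, perm)], atol=1e-10)
        np.testing.assert_allclose(fm_p.p, fm.p[np.ix_(perm, perm)], atol=1e-10)

    def test_planted_edges_carry_more_flow(self, network, small_flows):
        adj = network.adjacency
        off = ~np.eye(network.n_nodes, dtype=bool)
        f = np.mean([fm.f for fm in small_flows.values()], axis=0)
        assert f[adj].mean() > 5 * f[~adj & off].mean()

    def test_transformer_roundtrip_and_params(self, small_panels):
        panels, _ = small_panels
        est = ggc.GrangerGewekeFlow(lag_max=3)
        assert est.get_params()["lag_max"] == 3
        out = est.transform({"sub0000": panels["sub0000"]})
        assert set(out) == {"sub0000"}
        assert out["sub0000"].n_nodes == 20

    def test_single_node_panel_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            ggc.compute_flow_matrix(make_panel(rng.normal(size=(100, 1))), lag_max=2)
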