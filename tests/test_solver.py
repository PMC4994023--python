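"""ADMM trace-norm solver: proximal operator, block updates, and full fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugmtl import fit_path, fit_trace_norm, lambda_max_trace_norm, objective, svd_shrink
from drugmtl.solver import ADMMState, build_designs, dual_update, w_update, z_update

from _reference import optimal_intercepts, proxgrad_trace_norm


def _random_problem(seed, N=40, P=20, T=5, rank=2, noise=0.5, obs_frac=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((N, P))
    W0 = rng.standard_normal((P, rank)) @ rng.standard_normal((rank, T))
    Y = X @ W0 + rng.standard_normal(T) + noise * rng.standard_normal((N, T))
    mask = rng.random((N, T)) < obs_frac
    mask[:, mask.sum(0) == 0] = True
    return X, Y, mask


class TestSvdShrink:
    def test_diagonal_case(self):
        M = np.diag([3.0, 1.0])
        np.testing.assert_allclose(svd_shrink(M, 2.0), np.diag([1.0, 0.0]), atol=1e-12)

    def test_tau_zero_identity(self, rng):
        M = rng.standard_normal((6, 4))
        np.testing.assert_allclose(svd_shrink(M, 0.0), M, atol=1e-10)

    def test_singular_values_shrunk(self, rng):
        # oracle: independent SVD of the output
        for _ in range(10):
            M = rng.standard_normal((6, 4))
            tau = float(rng.uniform(0.1, 2.0))
            out = svd_shrink(M, tau)
            s_in = np.linalg.svd(M, compute_uv=False)
            s_out = np.linalg.svd(out, compute_uv=False)
            np.testing.assert_allclose(s_out, np.maximum(s_in - tau, 0.0), atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svd_shrink(np.array([[np.nan, 0.0], [0.0, 1.0]]), 0.5)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.0, 5.0))
    def test_output_trace_norm(self, seed, tau):
        M = np.random.default_rng(seed).standard_normal((5, 3))
        out = svd_shrink(M, tau)
        s = np.linalg.svd(M, compute_uv=False)
        assert np.sum(np.linalg.svd(out, compute_uv=False)) == pytest.approx(
            np.sum(np.maximum(s - tau, 0.0)), abs=1e-8
        )


class TestBlockUpdates:
    def test_w_update_large_rho_pins_to_z(self):
        X, Y, mask = _random_problem(0)
        designs = build_designs(X, Y, mask)
        P, T = X.shape[1], Y.shape[1]
        state = ADMMState(np.zeros((P, T)), np.zeros(T), np.zeros((P, T)),
                          np.zeros((P, T)), rho=1e8)
        W, b = w_update(state, designs)
        assert np.abs(W).max() < 1e-4
        for t, d in enumerate(designs):
            assert b[t] == pytest.approx(Y[mask[:, t], t].mean(), abs=1e-4)

    def test_w_update_matches_ridge_normal_equations(self, rng):
        # single task, Z=Gamma=0, rho=2: slope penalty (rho/2)||w||^2 = ||w||^2
        X = rng.standard_normal((25, 8))
        y = rng.standard_normal(25)
        designs = build_designs(X, y[:, None], np.ones((25, 1), bool))
        state = ADMMState(np.zeros((8, 1)), np.zeros(1), np.zeros((8, 1)),
                          np.zeros((8, 1)), rho=2.0)
        W, b = w_update(state, designs)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        w_ref = np.linalg.solve(2.0 * Xc.T @ Xc + 2.0 * np.eye(8), 2.0 * Xc.T @ yc)
        np.testing.assert_allclose(W[:, 0], w_ref, atol=1e-10)
        assert b[0] == pytest.approx(y.mean() - w_ref @ X.mean(0), abs=1e-10)

    def test_w_update_never_increases_augmented_objective(self):
        for seed in range(20):
            X, Y, mask = _random_problem(seed, N=25, P=10, T=3)
            designs = build_designs(X, Y, mask)
            rng = np.random.default_rng(seed + 100)
            P, T = 10, 3
            W0 = rng.standard_normal((P, T))
            b0 = rng.standard_normal(T)
            Z = rng.standard_normal((P, T))
            G = rng.standard_normal((P, T))
            state = ADMMState(W0, b0, Z, G, rho=1.5)

            def aug(W, b):
                loss = objective(X, Y, W, b, 0.0, mask)
                return loss + float(np.sum(G * (W - Z))) + 0.75 * float(
                    np.linalg.norm(W - Z) ** 2
                )

            W1, b1 = w_update(state, designs)
            assert aug(W1, b1) <= aug(W0, b0) + 1e-9

    def test_z_update_limits(self, rng):
        P, T = 6, 3
        W = rng.standard_normal((P, T))
        G = rng.standard_normal((P, T))
        state = ADMMState(W, np.zeros(T), np.zeros((P, T)), G, rho=2.0)
        np.testing.assert_allclose(z_update(state, 0.0), W + G / 2.0, atol=1e-10)
        smax = np.linalg.svd(W + G / 2.0, compute_uv=False)[0]
        assert np.all(z_update(state, 2.0 * smax * 1.01) == 0.0)

    def test_z_update_is_proximal_minimizer(self, rng):
        # random-search verification of proximal optimality on a 5x3 instance
        W = rng.standard_normal((5, 3))
        G = rng.standard_normal((5, 3))
        rho, lam = 1.3, 0.7
        state = ADMMState(W, np.zeros(3), np.zeros((5, 3)), G, rho=rho)
        Z = z_update(state, lam)
        M = W + G / rho

        def prox_obj(Zc):
            return lam * np.sum(np.linalg.svd(Zc, compute_uv=False)) + (
                rho / 2.0
            ) * np.linalg.norm(Zc - M) ** 2

        base = prox_obj(Z)
        for _ in range(1000):
            pert = Z + rng.standard_normal((5, 3)) * rng.choice([1e-3, 1e-2, 0.1, 1.0])
            assert prox_obj(pert) >= base - 1e-9

    def test_dual_update_contract(self, rng):
        P, T = 4, 2
        W = rng.standard_normal((P, T))
        G = rng.standard_normal((P, T))
        state = ADMMState(W, np.zeros(T), W.copy(), G, rho=3.0)
        np.testing.assert_array_equal(dual_update(state), G)  # W == Z
        E = rng.standard_normal((P, T))
        state = ADMMState(W, np.zeros(T), W - E, np.zeros((P, T)), rho=1.0)
        np.testing.assert_allclose(dual_update(state), E, atol=1e-12)
        # two successive updates compose additively
        state.Gamma = dual_update(state)
        np.testing.assert_allclose(dual_update(state), 2 * E, atol=1e-12)


class TestFitTraceNorm:
    def test_lambda_zero_matches_per_task_ols(self):
        X, Y, _ = _random_problem(3, N=30, P=10, T=4, obs_frac=1.0)
        m = fit_trace_norm(X, Y, 0.0, standardize=False)
        for t in range(4):
            Xc = X - X.mean(0)
            yc = Y[:, t] - Y[:, t].mean()
            w = np.linalg.lstsq(Xc, yc, rcond=None)[0]
            np.testing.assert_allclose(m.W[:, t], w, rtol=1e-5, atol=1e-8)

    def test_full_shrinkage_gives_zero_model(self):
        X, Y, mask = _random_problem(4, obs_frac=0.9)
        lam_max = lambda_max_trace_norm(X, Y, mask, standardize=False)
        m = fit_trace_norm(X, Y, 2.0 * lam_max, mask=mask, standardize=False)
        assert np.all(m.W == 0.0)
        for t in range(Y.shape[1]):
            assert m.b[t] == pytest.approx(Y[mask[:, t], t].mean(), abs=1e-8)

    def test_lambda_max_is_boundary(self):
        X, Y, mask = _random_problem(5)
        lam_max = lambda_max_trace_norm(X, Y, mask, standardize=False)
        above = fit_trace_norm(X, Y, 1.05 * lam_max, mask=mask, standardize=False)
        below = fit_trace_norm(X, Y, 0.7 * lam_max, mask=mask, standardize=False)
        assert np.all(above.W == 0.0)
        assert np.any(below.W != 0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_proximal_gradient_reference(self, seed):
        X, Y, mask = _random_problem(seed, N=40, P=25, T=6, obs_frac=0.85)
        lam = 0.1 * lambda_max_trace_norm(X, Y, mask, standardize=False)
        m = fit_trace_norm(X, Y, lam, mask=mask, standardize=False)
        W_ref, b_ref = proxgrad_trace_norm(X, Y, lam, mask)
        o_admm = objective(X, Y, m.W, m.b, lam, mask)
        o_ref = objective(X, Y, W_ref, b_ref, lam, mask)
        assert o_admm <= o_ref * (1 + 1e-4) + 1e-10

    def test_masked_entries_never_influence_fit(self):
        X, Y, mask = _random_problem(6, obs_frac=0.8)
        lam = 0.2 * lambda_max_trace_norm(X, Y, mask, standardize=False)
        m1 = fit_trace_norm(X, Y, lam, mask=mask)
        Y2 = Y.copy()
        Y2[~mask] = 1e6  # garbage in every hidden cell
        m2 = fit_trace_norm(X, Y2, lam, mask=mask)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.b, m2.b)

    def test_split_residual_small_at_convergence(self):
        X, Y, mask = _random_problem(7)
        lam = 0.1 * lambda_max_trace_norm(X, Y, mask, standardize=False)
        m = fit_trace_norm(X, Y, lam, mask=mask, standardize=False,
                           tol_abs=1e-6, tol_rel=1e-5)
        state = m._state
        assert np.linalg.norm(state.W - state.Z) <= 1e-3 * np.linalg.norm(state.Z)

    def test_standardized_fit_predicts_on_original_scale(self):
        X, Y, mask = _random_problem(8)
        X[:, 0] *= 100.0  # wildly different column scales
        lam = 0.05 * lambda_max_trace_norm(X, Y, mask)
        m = fit_trace_norm(X, Y, lam, mask=mask, standardize=True)
        pred = m.predict(X)
        assert np.isfinite(pred).all()
        resid = Y[mask] - pred[mask]
        base = Y[mask] - Y[mask].mean()
        assert np.sum(resid**2) < np.sum(base**2)

    def test_max_iter_warns_and_flags(self):
        X, Y, mask = _random_problem(9)
        lam = 0.05 * lambda_max_trace_norm(X, Y, mask, standardize=False)
        with pytest.warns(UserWarning, match="did not converge"):
            m = fit_trace_norm(X, Y, lam, mask=mask, standardize=False, max_iter=3)
        assert not m.converged


class TestFitPath:
    def test_singleton_path_equals_single_fit(self):
        X, Y, mask = _random_problem(10)
        lam = 0.3 * lambda_max_trace_norm(X, Y, mask, standardize=False)
        path = fit_path(X, Y, [lam], mask=mask, standardize=False)
        single = fit_trace_norm(X, Y, lam, mask=mask, standardize=False)
        np.testing.assert_allclose(path[0].W, single.W, atol=1e-10)

    def test_nonmonotone_sequence_rejected(self):
        X, Y, _ = _random_problem(11)
        with pytest.raises(ValueError, match="decreasing"):
            fit_path(X, Y, [1.0, 2.0])

    def test_warm_starts_do_not_cost_more_iterations(self):
        X, Y, mask = _random_problem(12)
        lam_max = lambda_max_trace_norm(X, Y, mask, standardize=False)
        grid = np.geomspace(lam_max * 0.9, lam_max * 0.02, 8)
        warm = fit_path(X, Y, grid, mask=mask, standardize=False)
        cold = [fit_trace_norm(X, Y, float(l), mask=mask, standardize=False) for l in grid]
        assert sum(m.n_iter for m in warm) <= sum(m.n_iter for m in cold)

    def test_path_objectives_beat_zero_model(self):
        X, Y, mask = _random_problem(13)
        lam_max = lambda_max_trace_norm(X, Y, mask, standardize=False)
        grid = np.geomspace(lam_max * 0.8, lam_max * 0.05, 6)
        b0 = optimal_intercepts(X, Y, np.zeros((X.shape[1], Y.shape[1])), mask)
        for m in fit_path(X, Y, grid, mask=mask, standardize=False):
            o_model = objective(X, Y, m.W, m.b, m.lam, mask)
            o_zero = objective(X, Y, np.zeros_like(m.W), b0, m.lam, mask)
            assert o_model <= o_zero + 1e-8

    def test_mean_rank_nonincreasing_in_lambda(self):
        ranks = np.zeros((10, 10))
        for i in range(10):
            X, Y, mask = _random_problem(100 + i, N=35, P=15, T=6, rank=3)
            lam_max = lambda_max_trace_norm(X, Y, mask, standardize=False)
            grid = np.geomspace(lam_max * 0.95, lam_max * 0.01, 10)
            models = fit_path(X, Y, grid, mask=mask, standardize=False)
            ranks[i] = [m.rank for m in models]
        mean_rank = ranks.mean(axis=0)  # grid is decreasing, so reverse
        assert np.all(np.diff(mean_rank[::-1]) <= 1e-9)
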