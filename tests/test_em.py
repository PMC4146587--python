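import numpy as np
import pytest

import varssm as v
from varssm.em import _row_coordinates, estep, mstep_dense, mstep_row_penalized
from conftest import random_dataset, random_params
from _oracles import brute_force_penalized_row, oracle_suffstats


def _random_stats(n, m, rng, n_trans=50, n_obs=60):
    """Synthetic PSD sufficient statistics for M-step tests."""
    d = n + m + 1
    X = rng.normal(0, 1, (3 * d, d))

    class S:
        pass

    st = S()
    st.n_genes, st.n_exo = n, m
    st.S11 = X.T @ X
    st.n_trans, st.n_obs, st.n_courses = n_trans, n_obs, 1
    W = rng.normal(0, 0.5, (n, d))
    st.S01 = W @ st.S11 + rng.normal(0, 2, (n, d))
    st.S00 = np.zeros((n, n))
    for i in range(n):
        st.S00[i, i] = st.S01[i] @ np.linalg.solve(st.S11, st.S01[i]) + rng.uniform(5, 20)
    st.obs_stats = rng.uniform(1, 5, n)
    st.init_mean_sum = rng.normal(0, 1, n)
    return st


class TestEstep:
    def test_matches_joint_gaussian_oracle(self, tiny_grid):
        rng = np.random.default_rng(20)
        p = random_params(2, 1, rng)
        d = random_dataset(2, 1, tiny_grid, rng)
        st = estep(p, d, tiny_grid)
        S11, S01, S00, obs = oracle_suffstats(p, d, tiny_grid)
        assert np.max(np.abs(st.S11 - S11)) < 1e-8
        assert np.max(np.abs(st.S01 - S01)) < 1e-8
        assert np.max(np.abs(st.S00 - S00)) < 1e-8
        assert np.max(np.abs(st.obs_stats - obs)) < 1e-8

    def test_degenerate_noise_pins_states_to_trajectory(self, tiny_grid):
        rng = np.random.default_rng(21)
        p = random_params(2, 0, rng)
        p.H[:] = 1e-12
        p.R[:] = 1e-12
        p.Sigma0[:] = 1e-12
        # observations generated exactly on the deterministic trajectory
        x = p.mu0.copy()
        y = {}
        traj = [x.copy()]
        for t in range(1, tiny_grid.n_times):
            x = v.transition_mean(p, x)
            traj.append(x.copy())
        for t, idx in zip(tiny_grid.t_obs, tiny_grid.obs_indices()):
            y[float(t)] = [traj[idx].copy()]
        d = v.TimeCourseDataset(genes=["a", "b"], y=y)
        sm = v.kalman_smooth(p, d, tiny_grid)
        assert np.max(np.abs(sm.mean - np.array(traj))) < 1e-5
        st = estep(p, d, tiny_grid)
        # second moments collapse to outer products of means
        mm = sum(np.outer(z, z) for z in sm.mean[1:])
        assert np.max(np.abs(st.S00 - mm)) < 1e-4

    def test_duplicating_course_doubles_statistics(self, tiny_grid):
        rng = np.random.default_rng(22)
        p = random_params(2, 1, rng)
        d = random_dataset(2, 1, tiny_grid, rng)
        s1 = estep(p, d, tiny_grid)
        s2 = estep(p, [d, d.copy()], tiny_grid)
        assert np.allclose(s2.S11, 2 * s1.S11)
        assert np.allclose(s2.S01, 2 * s1.S01)
        assert np.allclose(s2.obs_stats, 2 * s1.obs_stats)
        assert s2.n_trans == 2 * s1.n_trans


class TestMstepDense:
    def test_recovers_exact_coefficients_from_exact_moments(self):
        """Noise-free sufficient statistics built from a known linear map."""
        rng = np.random.default_rng(23)
        n, m = 3, 1
        d = n + m + 1
        W_true = rng.normal(0, 0.5, (n, d))
        Z = rng.normal(0, 1, (40, d))
        Z[:, -1] = 1.0
        X = Z @ W_true.T

        class S:
            pass

        st = S()
        st.n_genes, st.n_exo = n, m
        st.S11 = Z.T @ Z
        st.S01 = X.T @ Z
        st.S00 = X.T @ X
        st.obs_stats = np.zeros(n)
        st.n_trans, st.n_obs, st.n_courses = 40, 1, 1
        st.init_mean_sum = np.zeros(n)
        p = mstep_dense(st)
        W_hat = np.column_stack([p.F, p.B, p.b])
        assert np.max(np.abs(W_hat - W_true)) < 1e-6

    def test_maximizes_row_objective(self):
        rng = np.random.default_rng(24)
        st = _random_stats(2, 1, rng)
        p = mstep_dense(st)
        for i in range(2):
            w_pkg = np.concatenate([p.F[i], p.B[i], [p.b[i]]])
            allowed = np.ones(4, dtype=bool)
            w_opt, H_opt = brute_force_penalized_row(
                st.S11, st.S01[i], st.S00[i, i], st.n_trans, 0.0,
                np.zeros(4), allowed)
            assert np.max(np.abs(w_pkg - w_opt)) < 1e-5
            assert abs(p.H[i] - H_opt) < 1e-6

    def test_noise_estimates_nonnegative_under_fuzzing(self):
        rng = np.random.default_rng(25)
        for _ in range(100):
            st = _random_stats(2, 1, rng, n_trans=int(rng.integers(5, 50)))
            p = mstep_dense(st)
            assert np.all(p.H >= 0) and np.all(p.R >= 0)


class TestMstepRowPenalized:
    def test_huge_lambda_zeroes_all_penalized(self):
        rng = np.random.default_rng(26)
        st = _random_stats(3, 1, rng)
        pen = v.PenaltyConfig.default(3, 1, lam=1e9)
        w, aA, aB, H = mstep_row_penalized(st, 0, pen, H_init=1.0)
        assert aA == set() and aB == set()
        # unpenalized coordinates match their restricted exact solve
        free = [0, 4]
        w_free = np.linalg.solve(st.S11[np.ix_(free, free)], st.S01[0][free])
        assert np.max(np.abs(w[free] - w_free)) < 1e-6

    def test_zero_lambda_equals_dense_rows(self):
        rng = np.random.default_rng(27)
        st = _random_stats(3, 1, rng)
        dense = mstep_dense(st)
        pen = v.PenaltyConfig.default(3, 1, lam=0.0)
        for i in range(3):
            w, _, _, _ = mstep_row_penalized(st, i, pen, H_init=1.0)
            w_dense = np.concatenate([dense.F[i], dense.B[i], [dense.b[i]]])
            assert np.max(np.abs(w - w_dense)) < 1e-8

    @pytest.mark.parametrize("row", [0, 1, 2])
    def test_matches_brute_force_optimizer(self, row):
        """Weighted-L1 row solution vs an independent split-variable optimizer."""
        rng = np.random.default_rng(28 + row)
        st = _random_stats(3, 1, rng)
        pen = v.PenaltyConfig.default(3, 1, lam=0.7)
        pen.cA[row, (row + 1) % 3] = 0.5
        allowed, weight = _row_coordinates(3, 1, row, pen)
        w_opt, H_opt = brute_force_penalized_row(
            st.S11, st.S01[row], st.S00[row, row], st.n_trans, 0.7, weight, allowed)
        # iterate the package's block update to its fixed point
        w, H = None, H_opt
        w, aA, aB, H = mstep_row_penalized(st, row, pen, w_init=w_opt, H_init=H_opt)
        assert np.max(np.abs(w - w_opt)) < 1e-6
        assert abs(H - H_opt) < 1e-6

    def test_kkt_conditions_at_solution(self):
        rng = np.random.default_rng(31)
        st = _random_stats(3, 1, rng)
        lam = 0.4
        pen = v.PenaltyConfig.default(3, 1, lam=lam)
        w, aA, aB, H = mstep_row_penalized(st, 1, pen, H_init=1.0)
        for _ in range(200):  # run block updates to the joint fixed point
            w2, aA, aB, H2 = mstep_row_penalized(st, 1, pen, w_init=w, H_init=H)
            if np.max(np.abs(w2 - w)) < 1e-12 and abs(H2 - H) < 1e-12:
                w, H = w2, H2
                break
            w, H = w2, H2
        allowed, weight = _row_coordinates(3, 1, 1, pen)
        grad = st.S11 @ w - st.S01[1]  # d/dw of quad/2
        for j in np.flatnonzero(allowed):
            if weight[j] == 0:
                assert abs(grad[j]) < 1e-6 * (1 + abs(st.S01[1][j]))
            elif w[j] == 0:
                assert abs(grad[j]) <= lam * weight[j] * H + 1e-6
            else:
                assert abs(grad[j] + np.sign(w[j]) * lam * weight[j] * H) < 1e-6

    def test_vanishing_weight_approaches_unpenalized(self):
        """As the prior weight of one coordinate shrinks toward 0 its estimate
        converges to the solution with that coordinate exactly unpenalized
        (the other candidates stay penalized)."""
        rng = np.random.default_rng(32)
        st = _random_stats(3, 0, rng)
        pen_ref = v.PenaltyConfig.default(3, 0, lam=2.0)
        allowed, weight_ref = _row_coordinates(3, 0, 0, pen_ref)
        weight_ref = weight_ref.copy()
        weight_ref[1] = 0.0  # the oracle can use an exactly-unpenalized coordinate
        w_ref, _ = brute_force_penalized_row(
            st.S11 + 1e-10 * np.eye(4), st.S01[0], st.S00[0, 0],
            st.n_trans, 2.0, weight_ref, allowed)
        errs = []
        for wgt in (1.0, 1e-3, 1e-6):
            pen = v.PenaltyConfig.default(3, 0, lam=2.0)
            pen.cA[0, 1] = wgt
            w, H = np.zeros(4), 1.0
            for _ in range(500):  # block updates to the joint fixed point
                w2, _, _, H2 = mstep_row_penalized(st, 0, pen, w_init=w, H_init=H)
                if np.max(np.abs(w2 - w)) < 1e-13 and abs(H2 - H) < 1e-13:
                    w, H = w2, H2
                    break
                w, H = w2, H2
            errs.append(abs(w[1] - w_ref[1]))
        assert errs[-1] < 1e-3
        assert errs[-1] <= errs[0] + 1e-12

    def test_negative_lambda_rejected(self):
        rng = np.random.default_rng(33)
        st = _random_stats(2, 0, rng)
        pen = v.PenaltyConfig.default(2, 0)
        pen.lambda_n[0] = -0.5
        with pytest.raises(ValueError):
            mstep_row_penalized(st, 0, pen, H_init=1.0)


class TestEmFit:
    def test_fixed_point_at_generating_parameters(self, tiny_grid):
        """Noise-free data generated by the model: EM started at the truth
        stays there (trace flat, A unchanged)."""
        rng = np.random.default_rng(34)
        p = random_params(2, 0, rng)
        p.H[:] = 1e-8
        p.R[:] = 1e-8
        p.Sigma0[:] = 1e-8
        y = {}
        traj = [p.mu0.copy()]
        for t in range(1, tiny_grid.n_times):
            traj.append(v.transition_mean(p, traj[-1]))
        for t, idx in zip(tiny_grid.t_obs, tiny_grid.obs_indices()):
            y[float(t)] = [traj[idx].copy()]
        d = v.TimeCourseDataset(genes=["a", "b"], y=y)
        fit = v.em_fit(d, tiny_grid, init=p, max_iter=5, estimate_mu0=False)
        assert np.max(np.abs(fit.params.A - p.A)) < 5e-3

    def test_parameter_recovery_long_series(self):
        """3-gene system driven by its own system noise, T = 200: the dense
        EM estimate of A lands within 0.15 of the truth."""
        A = np.array([[-0.25, 0.0, 0.0], [0.35, -0.3, 0.0], [0.0, -0.3, -0.35]])
        b = np.array([1.0, 0.5, 2.0])
        truth = v.GRNParameters(A=A, B=np.zeros((3, 0)), b=b,
                                H=np.full(3, 0.25), R=np.full(3, 0.01),
                                mu0=np.linalg.solve(A, -b), Sigma0=np.full(3, 0.25))
        grid = v.TimeGrid.from_observed(np.arange(200.0), k=1)
        rng = np.random.default_rng(42)
        x = truth.mu0.copy()
        y = {}
        for t in range(200):
            if t > 0:
                x = truth.F @ x + truth.b + rng.normal(0, np.sqrt(truth.H))
            y[float(t)] = [x + rng.normal(0, np.sqrt(truth.R))]
        d = v.TimeCourseDataset(genes=["a", "b", "c"], y=y)
        fit = v.em_fit(d, grid, max_iter=600)
        assert np.max(np.abs(fit.params.A - A)) < 0.15

    def test_trace_is_monotone(self, cascade_data, obs_grid):
        pen = v.PenaltyConfig.default(5, 1, lam=2.0)
        fit = v.em_fit(cascade_data, obs_grid, pen, max_iter=60)
        t = np.array(fit.reg_loglik_trace)
        assert np.all(np.diff(t) >= -1e-6 * (1 + np.abs(t[:-1])))


class TestRegularizedLoglik:
    def test_no_penalty_equals_filter_loglik(self, tiny_grid):
        rng = np.random.default_rng(35)
        p = random_params(2, 1, rng)
        d = random_dataset(2, 1, tiny_grid, rng)
        rl = v.regularized_loglik(p, d, tiny_grid, None)
        assert abs(rl - v.kalman_filter(p, d, tiny_grid).loglik) < 1e-12

    def test_zero_matrices_zero_penalty(self, tiny_grid):
        rng = np.random.default_rng(36)
        p = random_params(2, 1, rng)
        p.A[0, 1] = p.A[1, 0] = 0.0
        p.B[:] = 0.0
        pen = v.PenaltyConfig.default(2, 1, lam=3.0)
        d = random_dataset(2, 1, tiny_grid, rng)
        assert abs(v.regularized_loglik(p, d, tiny_grid, pen)
                   - v.kalman_filter(p, d, tiny_grid).loglik) < 1e-12

    def test_matches_hand_summed_penalty(self, tiny_grid):
        rng = np.random.default_rng(37)
        p = random_params(3, 1, rng)
        pen = v.PenaltyConfig.default(3, 1, lam=0.9)
        pen.cA[0, 1] = 0.4
        d = random_dataset(3, 1, tiny_grid, rng)
        hand = 0.0
        for i in range(3):
            for j in pen.candidate_A[i]:
                hand += 0.9 * pen.cA[i, j] * abs(p.A[i, j])
            for j in pen.candidate_B[i]:
                hand += 0.9 * pen.cB[i, j] * abs(p.B[i, j])
        ll = v.kalman_filter(p, d, tiny_grid).loglik
        assert abs(v.regularized_loglik(p, d, tiny_grid, pen) - (ll - hand)) < 1e-10
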