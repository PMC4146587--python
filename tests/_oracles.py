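"""Independent brute-force oracles used by the test suite.

Everything here is built by explicit construction of the joint Gaussian over
all hidden states and observations (no recursions), or by generic numerical
optimization — deliberately independent of the package's filter/smoother/EM
code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from varssm.kalman import observations_by_grid_index
from varssm.model_core import GRNParameters, TimeCourseDataset, TimeGrid


def joint_gaussian(params: GRNParameters, data: TimeCourseDataset, grid: TimeGrid):
    """Exact joint distribution of (stacked states, stacked observations).

    Returns (mean_x (T*N,), cov_x (T*N, T*N), obs_index list, mean_y, cov_xy,
    cov_y, y_stacked) where obs_index[i] is the grid time of the i-th
    observation vector.
    """
    n = params.n_genes
    T = grid.n_times
    F = params.F
    Hd = np.diag(params.H)
    u = data.u_on_grid(grid)

    mean = np.zeros((T, n))
    mean[0] = params.mu0
    for t in range(1, T):
        mean[t] = F @ mean[t - 1] + params.b
        if params.n_exo:
            mean[t] += params.B @ u[t - 1]

    C = np.zeros((T, T, n, n))
    C[0, 0] = np.diag(params.Sigma0)
    for t in range(1, T):
        C[t, t] = F @ C[t - 1, t - 1] @ F.T + Hd
        for s in range(t):
            C[t, s] = F @ C[t - 1, s]
            C[s, t] = C[t, s].T

    cov_x = np.block([[C[t, s] for s in range(T)] for t in range(T)])
    mean_x = mean.reshape(-1)

    obs = observations_by_grid_index(data, grid)
    obs_times, ys = [], []
    for t in sorted(obs):
        for y in obs[t]:
            obs_times.append(t)
            ys.append(y)
    k = len(obs_times)
    mean_y = np.concatenate([mean[t] for t in obs_times]) if k else np.zeros(0)
    cov_y = np.zeros((k * n, k * n))
    cov_xy = np.zeros((T * n, k * n))
    for i, ti in enumerate(obs_times):
        for j, tj in enumerate(obs_times):
            blk = C[ti, tj].copy()
            if i == j:
                blk += np.diag(params.R)
            cov_y[i * n:(i + 1) * n, j * n:(j + 1) * n] = blk
        for t in range(T):
            cov_xy[t * n:(t + 1) * n, i * n:(i + 1) * n] = C[t, ti]
    y_stacked = np.concatenate(ys) if k else np.zeros(0)
    return mean_x, cov_x, obs_times, mean_y, cov_xy, cov_y, y_stacked


def oracle_loglik(params, data, grid) -> float:
    """Marginal log-density of all stacked observations."""
    _, _, _, mean_y, _, cov_y, y = joint_gaussian(params, data, grid)
    if y.size == 0:
        return 0.0
    return float(stats.multivariate_normal.logpdf(y, mean_y, cov_y, allow_singular=True))


def oracle_smoothed(params, data, grid):
    """Posterior mean/cov of all states given all data, by Gaussian conditioning.

    Returns (mean (T, N), cov (T, N, N), lag1 (T, N, N)) with
    lag1[t] = Cov(x_t, x_{t-1} | data).
    """
    n = params.n_genes
    T = grid.n_times
    mean_x, cov_x, _, mean_y, cov_xy, cov_y, y = joint_gaussian(params, data, grid)
    if y.size:
        sol = np.linalg.solve(cov_y, (y - mean_y))
        post_mean = mean_x + cov_xy @ sol
        post_cov = cov_x - cov_xy @ np.linalg.solve(cov_y, cov_xy.T)
    else:
        post_mean, post_cov = mean_x, cov_x
    mean = post_mean.reshape(T, n)
    cov = np.empty((T, n, n))
    lag1 = np.zeros((T, n, n))
    for t in range(T):
        cov[t] = post_cov[t * n:(t + 1) * n, t * n:(t + 1) * n]
        if t > 0:
            lag1[t] = post_cov[t * n:(t + 1) * n, (t - 1) * n:t * n]
    return mean, cov, lag1


def oracle_suffstats(params, data, grid):
    """Sufficient statistics (S11, S01, S00, obs_stats) from the exact posterior."""
    n, m = params.n_genes, params.n_exo
    T = grid.n_times
    mean_x, cov_x, _, mean_y, cov_xy, cov_y, y = joint_gaussian(params, data, grid)
    sol = np.linalg.solve(cov_y, (y - mean_y))
    post_mean = (mean_x + cov_xy @ sol).reshape(T, n)
    post_cov = cov_x - cov_xy @ np.linalg.solve(cov_y, cov_xy.T)
    u = data.u_on_grid(grid)
    d = n + m + 1
    S11 = np.zeros((d, d))
    S01 = np.zeros((n, d))
    S00 = np.zeros((n, n))

    def blk(t, s):
        return post_cov[t * n:(t + 1) * n, s * n:(s + 1) * n]

    for t in range(1, T):
        z = np.concatenate([post_mean[t - 1], u[t - 1], [1.0]])
        Ezz = np.outer(z, z)
        Ezz[:n, :n] += blk(t - 1, t - 1)
        S11 += Ezz
        Exz = np.outer(post_mean[t], z)
        Exz[:, :n] += blk(t, t - 1)
        S01 += Exz
        S00 += blk(t, t) + np.outer(post_mean[t], post_mean[t])

    obs = observations_by_grid_index(data, grid)
    obs_stats = np.zeros(n)
    for t, reps in obs.items():
        v = np.diag(blk(t, t))
        for yy in reps:
            obs_stats += (yy - post_mean[t]) ** 2 + v
    return S11, S01, S00, obs_stats


def penalized_row_objective(G, s, c00, n_trans, lam, weights, allowed):
    """Row objective as a function of (w, H): the expected negative
    log-likelihood of the row's transitions plus the weighted L1 term."""

    def f(w, H):
        quad = w @ G @ w - 2.0 * s @ w + c00
        nll = 0.5 * n_trans * np.log(2 * np.pi * H) + quad / (2 * H)
        return nll + lam * float(np.abs(w[allowed]) @ weights[allowed]) \
            if weights is not None else nll

    return f


def brute_force_penalized_row(G, s, c00, n_trans, lam, weights, allowed):
    """Exact minimizer of the penalized row problem via a smooth split
    formulation (w = p - q, p,q >= 0) solved by L-BFGS-B, profiling out H.

    Independent of the package's coordinate descent.
    """
    d = G.shape[0]
    idx = np.flatnonzero(allowed)
    k = idx.size

    def unpack(z):
        w = np.zeros(d)
        w[idx] = z[:k] - z[k:]
        return w

    def obj(z):
        w = unpack(z)
        quad = w @ G @ w - 2.0 * s @ w + c00
        H = max(quad / n_trans, 1e-12)
        nll = 0.5 * n_trans * (np.log(2 * np.pi * H) + 1.0)
        pen = lam * float((z[:k] + z[k:]) @ weights[idx])
        return nll + pen

    z0 = np.zeros(2 * k)
    best = None
    for trial in range(3):
        res = optimize.minimize(obj, z0 + 0.01 * trial, method="L-BFGS-B",
                                bounds=[(0, None)] * (2 * k),
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    w = unpack(best.x)
    quad = w @ G @ w - 2.0 * s @ w + c00
    return w, max(quad / n_trans, 1e-12)
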