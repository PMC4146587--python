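"""Kalman filtering and fixed-interval smoothing for the network state-space model.

The hidden state lives on the full sub-stepped grid; observations (possibly
replicated, with the identity observation map and diagonal noise) occur only
at the observed subset.  Replicates at a time point are absorbed by
sequential scalar-time updates, which is exactly equivalent to stacking them
but never forms an rN x rN system.  Covariance updates use the Joseph form
and are re-symmetrized after every step.

The recursions are plain loops compiled with numba when it is available
(they are sequential by nature, so vectorization cannot help); without numba
the same code runs as ordinary Python.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import GRNParameters, TimeCourseDataset, TimeGrid

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["FilterResult", "SmoothedMoments", "kalman_filter", "kalman_smooth"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FilterResult:
    """Predicted and filtered moments per grid time plus the data log-likelihood."""

    pred_mean: np.ndarray  # (T, N)
    pred_cov: np.ndarray   # (T, N, N)
    filt_mean: np.ndarray
    filt_cov: np.ndarray
    loglik: float


@dataclass
class SmoothedMoments:
    """Posterior moments of the hidden state given all data.

    ``lag1[t]`` is Cov(x_t, x_{t-1} | all data) for t >= 1 (``lag1[0]`` is zero).
    """

    mean: np.ndarray   # (T, N)
    cov: np.ndarray    # (T, N, N)
    lag1: np.ndarray   # (T, N, N)


def observations_by_grid_index(data: TimeCourseDataset, grid: TimeGrid) -> dict[int, np.ndarray]:
    """Map grid index -> (r, N) replicate matrix for every observed time with data."""
    out: dict[int, np.ndarray] = {}
    idx = {float(t): i for t, i in zip(grid.t_obs, grid.obs_indices())}
    for t, reps in data.y.items():
        if float(t) not in idx:
            raise ValueError(f"data at t={t} is not on the grid's observed set")
        if reps:
            out[idx[float(t)]] = np.vstack(reps)
    return out


def _flatten_obs(obs: dict[int, np.ndarray], T: int, n: int):
    """Observation vectors in grid order plus a CSR-style pointer per grid time."""
    ptr = np.zeros(T + 1, dtype=np.int64)
    for t in range(T):
        ptr[t + 1] = ptr[t] + (obs[t].shape[0] if t in obs else 0)
    vals = np.empty((ptr[-1], n))
    for t, block in obs.items():
        vals[ptr[t]:ptr[t + 1]] = block
    return vals, ptr


@njit(cache=True)
def _chol(S):  # pragma: no cover - jitted
    """Lower Cholesky factor of a small SPD matrix (loop implementation:
    avoids per-call LAPACK overhead, which dominates at network sizes)."""
    n = S.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            acc = S[i, j]
            for k in range(j):
                acc -= L[i, k] * L[j, k]
            if i == j:
                if acc <= 0.0:
                    raise ValueError("matrix not positive definite")
                L[i, i] = np.sqrt(acc)
            else:
                L[i, j] = acc / L[j, j]
    return L


@njit(cache=True)
def _chol_solve_mat(L, B):  # pragma: no cover - jitted
    """Solve (L L') X = B for matrix B via forward/back substitution."""
    n = L.shape[0]
    m = B.shape[1]
    X = B.copy()
    for c in range(m):
        for i in range(n):
            acc = X[i, c]
            for k in range(i):
                acc -= L[i, k] * X[k, c]
            X[i, c] = acc / L[i, i]
        for i in range(n - 1, -1, -1):
            acc = X[i, c]
            for k in range(i + 1, n):
                acc -= L[k, i] * X[k, c]
            X[i, c] = acc / L[i, i]
    return X


@njit(cache=True)
def _filter_core(F, drift, Hd, R, mu0, S0, yvals, yptr):  # pragma: no cover - jitted
    T = drift.shape[0]
    n = mu0.shape[0]
    pred_mean = np.empty((T, n))
    pred_cov = np.empty((T, n, n))
    filt_mean = np.empty((T, n))
    filt_cov = np.empty((T, n, n))
    Rd = np.diag(R)
    eye = np.eye(n)
    loglik = 0.0
    m = mu0.copy()
    V = np.diag(S0).copy()
    for t in range(T):
        if t > 0:
            m = F @ filt_mean[t - 1] + drift[t]
            V = F @ filt_cov[t - 1] @ F.T + Hd
            V = 0.5 * (V + V.T)
        pred_mean[t] = m
        pred_cov[t] = V
        for r in range(yptr[t], yptr[t + 1]):
            y = yvals[r]
            S = V + Rd
            S = 0.5 * (S + S.T)
            L = _chol(S)
            e = y - m
            # alpha = L^{-1} e ; loglik uses the innovation density
            alpha = e.copy()
            ld = 0.0
            for i in range(n):
                acc = alpha[i]
                for k in range(i):
                    acc -= L[i, k] * alpha[k]
                alpha[i] = acc / L[i, i]
                ld += np.log(L[i, i])
            loglik += -0.5 * n * _LOG2PI - ld - 0.5 * (alpha @ alpha)
            K = _chol_solve_mat(L, V).T  # K = V S^{-1}
            m = m + K @ e
            IK = eye - K
            V = IK @ V @ IK.T + K @ Rd @ K.T  # Joseph form
            V = 0.5 * (V + V.T)
        filt_mean[t] = m
        filt_cov[t] = V
    return pred_mean, pred_cov, filt_mean, filt_cov, loglik


@njit(cache=True)
def _smooth_core(F, pred_mean, pred_cov, filt_mean, filt_cov):  # pragma: no cover
    T, n = filt_mean.shape
    mean = filt_mean.copy()
    cov = filt_cov.copy()
    lag1 = np.zeros((T, n, n))
    for t in range(T - 2, -1, -1):
        Vp = pred_cov[t + 1]
        L = _chol(Vp)
        J = _chol_solve_mat(L, F @ filt_cov[t]).T  # V_{t|t} F' Vp^{-1}
        mean[t] = filt_mean[t] + J @ (mean[t + 1] - pred_mean[t + 1])
        C = filt_cov[t] + J @ (cov[t + 1] - Vp) @ J.T
        cov[t] = 0.5 * (C + C.T)
        lag1[t + 1] = cov[t + 1] @ J.T
    return mean, cov, lag1


def _prepare(params: GRNParameters, data: TimeCourseDataset, grid: TimeGrid):
    n = params.n_genes
    if data.n_genes != n:
        raise ValueError(f"data has {data.n_genes} genes, params {n}")
    T = grid.n_times
    u = data.u_on_grid(grid)
    if u.shape[1] != params.n_exo:
        raise ValueError(f"data has {u.shape[1]} exogenous inputs, params {params.n_exo}")
    drift = np.tile(params.b, (T, 1))
    if params.n_exo:
        drift[1:] += u[:-1] @ params.B.T
    drift[0] = 0.0
    obs = observations_by_grid_index(data, grid)
    yvals, yptr = _flatten_obs(obs, T, n)
    if not np.all(np.isfinite(yvals)):
        raise ValueError("non-finite observation")
    return drift, yvals, yptr


def kalman_filter(params: GRNParameters, data: TimeCourseDataset,
                  grid: TimeGrid) -> FilterResult:
    """Forward pass: predicted/filtered moments and the observed-data log-likelihood."""
    drift, yvals, yptr = _prepare(params, data, grid)
    try:
        pm, pc, fm, fc, ll = _filter_core(
            params.F, drift, np.diag(params.H), params.R,
            params.mu0, params.Sigma0, yvals, yptr)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "innovation covariance not positive definite") from exc
    return FilterResult(pm, pc, fm, fc, float(ll))


def kalman_smooth(params: GRNParameters, data: TimeCourseDataset,
                  grid: TimeGrid, filt: FilterResult | None = None) -> SmoothedMoments:
    """Fixed-interval (RTS) smoother with lag-one covariances.

    The smoother gain J_t = V_{t|t} F' V_{t+1|t}^{-1} also yields the exact
    lag-one covariance Cov(x_{t+1}, x_t | all data) = V_{t+1|T} J_t'.
    """
    if filt is None:
        filt = kalman_filter(params, data, grid)
    mean, cov, lag1 = _smooth_core(params.F, filt.pred_mean, filt.pred_cov,
                                   filt.filt_mean, filt.filt_cov)
    return SmoothedMoments(mean, cov, lag1)
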