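"""EM estimation of the network parameters under weighted L1 regularization.

The E-step reduces the model to sufficient statistics over the augmented
regressor z_{t-1} = (x_{t-1}, u_{t-1}, 1) using smoothed means, covariances
and lag-one covariances.  Given those moments the expected complete-data
log-likelihood decomposes row-wise over genes: each row of (F, B, b) solves a
penalized weighted least-squares problem with Gram matrix S11, and the
diagonal noise variances H, R and the initial mean mu0 follow in closed form.
The L1 penalty (level lambda_n, per-coordinate weights in (0,1] for known
regulations) is applied by cyclic coordinate descent with soft thresholding;
the diagonal of A (degradation) and the synthesis intercept are never
penalized, and coordinates outside the candidate sets are held at zero.
Sigma0 is held fixed rather than estimated, which keeps the initial law
identifiable when only one or two short courses are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kalman import kalman_filter, kalman_smooth, njit, observations_by_grid_index
from .model_core import GRNParameters, PenaltyConfig, TimeCourseDataset, TimeGrid

__all__ = [
    "SufficientStatistics",
    "FitResult",
    "estep",
    "mstep_dense",
    "mstep_row_penalized",
    "em_fit",
    "regularized_loglik",
    "default_init",
]

NOISE_FLOOR = 1e-8
RIDGE = 1e-10
CD_TOL = 1e-8
CD_MAX_SWEEPS = 200


def _as_courses(data) -> list[TimeCourseDataset]:
    if isinstance(data, TimeCourseDataset):
        return [data]
    return list(data)


@dataclass
class SufficientStatistics:
    """Expected sufficient statistics of the complete-data log-likelihood.

    With z = (x, u, 1) of dimension d = N + M + 1:
      S11 = sum_t E[z_{t-1} z_{t-1}'],  S01 = sum_t E[x_t z_{t-1}'],
      S00 = sum_t E[x_t x_t'] (transition targets only),
      obs_stats[n] = sum over replicate observations of E[(y_n - x_n)^2].
    """

    S11: np.ndarray
    S01: np.ndarray
    S00: np.ndarray
    obs_stats: np.ndarray
    n_trans: int
    n_obs: int
    n_courses: int
    init_mean_sum: np.ndarray
    n_genes: int
    n_exo: int
    loglik: float = 0.0


def estep(params: GRNParameters, data, grid: TimeGrid) -> SufficientStatistics:
    """Assemble sufficient statistics from the Kalman smoother (summed over courses)."""
    courses = _as_courses(data)
    n, m = params.n_genes, params.n_exo
    d = n + m + 1
    S11 = np.zeros((d, d))
    S01 = np.zeros((n, d))
    S00 = np.zeros((n, n))
    obs_stats = np.zeros(n)
    init_mean_sum = np.zeros(n)
    n_trans = n_obs = 0
    loglik = 0.0

    for course in courses:
        filt = kalman_filter(params, course, grid)
        sm = kalman_smooth(params, course, grid, filt)
        loglik += filt.loglik
        u = course.u_on_grid(grid)
        T = grid.n_times
        Z = np.column_stack([sm.mean[:-1], u[:-1], np.ones(T - 1)])
        S11 += Z.T @ Z
        S11[:n, :n] += sm.cov[:-1].sum(axis=0)
        S01 += sm.mean[1:].T @ Z
        S01[:, :n] += sm.lag1[1:].sum(axis=0)
        S00 += sm.mean[1:].T @ sm.mean[1:] + sm.cov[1:].sum(axis=0)
        obs = observations_by_grid_index(course, grid)
        for t, reps in obs.items():
            v = np.diag(sm.cov[t])
            for y in reps:
                obs_stats += (y - sm.mean[t]) ** 2 + v
                n_obs += 1
        n_trans += T - 1
        init_mean_sum += sm.mean[0]

    return SufficientStatistics(S11, S01, S00, obs_stats, n_trans, n_obs,
                                len(courses), init_mean_sum, n, m, loglik)


def mstep_dense(stats: SufficientStatistics, sigma0=1.0) -> GRNParameters:
    """Closed-form unpenalized M-step: per-row solve plus closed-form noise updates."""
    n, m = stats.n_genes, stats.n_exo
    d = n + m + 1
    G = stats.S11 + RIDGE * np.eye(d)
    try:
        W = np.linalg.solve(G, stats.S01.T).T  # (n, d) rows of (F, B, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("normal equations singular even after ridge") from exc
    H = np.empty(n)
    for i in range(n):
        quad = stats.S00[i, i] - 2.0 * W[i] @ stats.S01[i] + W[i] @ stats.S11 @ W[i]
        H[i] = max(quad / stats.n_trans, NOISE_FLOOR)
    R = np.maximum(stats.obs_stats / max(stats.n_obs, 1), NOISE_FLOOR)
    mu0 = stats.init_mean_sum / stats.n_courses
    sigma0 = np.broadcast_to(np.asarray(sigma0, dtype=float), (n,)).copy()
    return GRNParameters(A=W[:, :n] - np.eye(n), B=W[:, n:n + m], b=W[:, d - 1],
                         H=H, R=R, mu0=mu0, Sigma0=sigma0)


def _row_coordinates(n: int, m: int, row_n: int, penalty: PenaltyConfig):
    """Allowed coordinate indices and per-coordinate penalty weights for one row.

    Coordinate layout: 0..n-1 -> F row (off-diagonal F = off-diagonal A),
    n..n+m-1 -> B row, n+m -> intercept.  Weight 0 marks unpenalized coords.
    """
    d = n + m + 1
    allowed = np.zeros(d, dtype=bool)
    weight = np.zeros(d)
    allowed[row_n] = True          # degradation: always in, never penalized
    allowed[d - 1] = True          # synthesis intercept
    for j in penalty.candidate_A[row_n]:
        allowed[j] = True
        weight[j] = penalty.cA[row_n, j]
    for j in penalty.candidate_B[row_n]:
        allowed[n + j] = True
        weight[n + j] = penalty.cB[row_n, j]
    return allowed, weight


@njit(cache=True)
def _coord_descent(G, s, w0, allowed, thresh):  # pragma: no cover - jitted
    """Minimize (1/2) w'Gw - s'w + sum_j thresh_j |w_j| over allowed coords.

    Maintains the residual G w incrementally; unpenalized coordinates use the
    plain Gauss-Seidel update, penalized ones soft thresholding.
    """
    d = w0.shape[0]
    w = np.zeros(d)
    for j in range(d):
        if allowed[j]:
            w[j] = w0[j]
    Gw = G @ w
    scale = max(np.max(np.abs(w)), 1.0)
    for _ in range(CD_MAX_SWEEPS):
        delta = 0.0
        for j in range(d):
            if not allowed[j]:
                continue
            gjj = G[j, j]
            r = s[j] - Gw[j] + gjj * w[j]
            if gjj <= 1e-14:
                new = 0.0
            elif thresh[j] > 0.0:
                a = abs(r) - thresh[j]
                new = (np.sign(r) * a / gjj) if a > 0.0 else 0.0
            else:
                new = r / gjj
            step = new - w[j]
            if step != 0.0:
                Gw += G[:, j] * step
                w[j] = new
                if abs(step) > delta:
                    delta = abs(step)
        if delta < CD_TOL * scale:
            break
    return w


def mstep_row_penalized(stats: SufficientStatistics, row_n: int,
                        penalty: PenaltyConfig, w_init: np.ndarray | None = None,
                        H_init: float = 1.0):
    """Penalized M-step for one gene row.

    Minimizes the row's expected negative log-likelihood plus
    lambda_n * sum_j c_j |coef_j| over the candidate coordinates, by cyclic
    coordinate descent with soft thresholding, alternating with the
    closed-form update of the system-noise variance H_n (the penalty enters
    the Q-scale through H_n, so the effective threshold is lambda_n c_j H_n).

    Returns ``(w, active_A, active_B, H_n)`` where ``w`` holds the row of
    (F, B, intercept).
    """
    lam = float(penalty.lambda_n[row_n])
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    n, m = stats.n_genes, stats.n_exo
    d = n + m + 1
    allowed, weight = _row_coordinates(n, m, row_n, penalty)
    G = stats.S11 + RIDGE * np.eye(d)
    s = stats.S01[row_n]
    w = np.zeros(d) if w_init is None else np.asarray(w_init, dtype=float).copy()
    H_n = max(float(H_init), NOISE_FLOOR)
    if lam == 0.0 or not np.any(weight[allowed] > 0):
        # unpenalized: exact restricted least squares, H in closed form
        idx = np.flatnonzero(allowed)
        w = np.zeros(d)
        w[idx] = np.linalg.solve(G[np.ix_(idx, idx)], s[idx])
        quad = stats.S00[row_n, row_n] - 2.0 * w @ s + w @ stats.S11 @ w
        H_n = max(quad / stats.n_trans, NOISE_FLOOR)
        active_A = {j for j in penalty.candidate_A[row_n] if w[j] != 0.0}
        active_B = {j for j in penalty.candidate_B[row_n] if w[n + j] != 0.0}
        return w, active_A, active_B, H_n

    # Note the joint (w, H_n) row problem is non-convex: the effective soft
    # threshold lam*c*H_n shrinks with H_n, so a dense small-H solution and a
    # sparse large-H solution can both be self-consistent.  A single block
    # update per M-step (coefficients at the incoming H_n, then the
    # closed-form H_n) keeps EM ascent while letting the noise scale adapt
    # gradually across EM iterations instead of avalanching within one; the
    # penalty path additionally starts every row at its all-zero
    # configuration so it tracks the sparse branch.
    c00 = stats.S00[row_n, row_n]
    w = _coord_descent(G, s, w, allowed, lam * weight * H_n)
    quad = c00 - 2.0 * w @ s + w @ stats.S11 @ w
    H_n = max(quad / stats.n_trans, NOISE_FLOOR)
    active_A = {j for j in penalty.candidate_A[row_n] if w[j] != 0.0}
    active_B = {j for j in penalty.candidate_B[row_n] if w[n + j] != 0.0}
    return w, active_A, active_B, H_n


def penalty_value(params: GRNParameters, penalty: PenaltyConfig | None) -> float:
    """Weighted L1 penalty sum over all penalized (candidate) coordinates."""
    if penalty is None:
        return 0.0
    total = 0.0
    for i in range(params.n_genes):
        lam = penalty.lambda_n[i]
        if lam == 0:
            continue
        for j in penalty.candidate_A[i]:
            total += lam * penalty.cA[i, j] * abs(params.A[i, j])
        for j in penalty.candidate_B[i]:
            total += lam * penalty.cB[i, j] * abs(params.B[i, j])
    return total


def regularized_loglik(params: GRNParameters, data, grid: TimeGrid,
                       penalty: PenaltyConfig | None = None) -> float:
    """Observed-data log-likelihood minus the weighted L1 penalty."""
    ll = sum(kalman_filter(params, c, grid).loglik for c in _as_courses(data))
    return ll - penalty_value(params, penalty)


def default_init(data, grid: TimeGrid, sigma0: float = 1.0) -> GRNParameters:
    """Data-scaled starting point: no regulation, noise from marginal variances."""
    courses = _as_courses(data)
    n = courses[0].n_genes
    m = courses[0].n_exo
    allobs = np.vstack([y for c in courses for reps in c.y.values() for y in reps])
    var = np.maximum(np.var(allobs, axis=0), 1e-4)
    first = np.mean([c.y[min(c.y)][0] for c in courses], axis=0)
    return GRNParameters(
        A=-0.1 * np.eye(n), B=np.zeros((n, m)),
        b=0.1 * np.mean(allobs, axis=0),
        H=0.5 * var, R=0.5 * var,
        mu0=np.asarray(first, dtype=float),
        Sigma0=np.full(n, sigma0),
    )


@dataclass
class FitResult:
    params: GRNParameters
    active_A: list[set[int]]
    active_B: list[set[int]]
    reg_loglik_trace: list[float]
    loglik: float
    converged: bool
    n_iter: int
    stats: SufficientStatistics | None = None


def _active_sets(params: GRNParameters, penalty: PenaltyConfig):
    aA = [{j for j in penalty.candidate_A[i] if params.A[i, j] != 0.0}
          for i in range(params.n_genes)]
    aB = [{j for j in penalty.candidate_B[i] if params.B[i, j] != 0.0}
          for i in range(params.n_genes)]
    return aA, aB


def em_fit(data, grid: TimeGrid, penalty: PenaltyConfig | None = None,
           init: GRNParameters | None = None, tol: float = 1e-6,
           max_iter: int = 500, update_rows: Sequence[int] | None = None,
           estimate_mu0: bool = True) -> FitResult:
    """EM ascent on the L1-regularized observed-data log-likelihood.

    ``update_rows`` restricts the M-step to the given gene rows (all other
    parameters frozen), which is how the structure search optimizes one row
    at a time.  Raises ``RuntimeError`` if the regularized log-likelihood
    decreases by more than a small slack — that indicates a broken M-step,
    not a tolerable numerical wobble.
    """
    courses = _as_courses(data)
    params = (default_init(courses, grid) if init is None else init.copy())
    if not all(np.all(np.isfinite(v)) for v in
               (params.A, params.B, params.b, params.H, params.R, params.mu0)):
        raise ValueError("non-finite initial parameters")
    n, m = params.n_genes, params.n_exo
    if penalty is None:
        penalty = PenaltyConfig.default(n, m, lam=0.0)
    rows = list(range(n)) if update_rows is None else [int(r) for r in update_rows]
    # coordinates outside candidate sets must start at zero or stay frozen
    for i in rows:
        drop_A = set(range(n)) - {i} - penalty.candidate_A[i]
        params.A[i, list(drop_A)] = 0.0
        drop_B = set(range(m)) - penalty.candidate_B[i]
        params.B[i, list(drop_B)] = 0.0

    trace: list[float] = []
    converged = False
    stats = None
    it = 0
    for it in range(1, max_iter + 1):
        stats = estep(params, courses, grid)
        rl = stats.loglik - penalty_value(params, penalty)
        if trace and rl < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
            raise RuntimeError(
                f"regularized log-likelihood decreased ({trace[-1]:.8g} -> {rl:.8g}); "
                "M-step is inconsistent with the E-step")
        if trace and abs(rl - trace[-1]) < tol * (1.0 + abs(trace[-1])):
            trace.append(rl)
            converged = True
            break
        trace.append(rl)
        for i in rows:
            w0 = np.concatenate([params.F[i], params.B[i], [params.b[i]]])
            w, _, _, H_i = mstep_row_penalized(stats, i, penalty, w_init=w0,
                                               H_init=params.H[i])
            params.A[i] = w[:n]
            params.A[i, i] = w[i] - 1.0
            params.B[i] = w[n:n + m]
            params.b[i] = w[n + m]
            params.H[i] = H_i
            params.R[i] = max(stats.obs_stats[i] / max(stats.n_obs, 1), NOISE_FLOOR)
            if estimate_mu0:
                params.mu0[i] = stats.init_mean_sum[i] / stats.n_courses
    aA, aB = _active_sets(params, penalty)
    final_ll = sum(kalman_filter(params, c, grid).loglik for c in courses)
    return FitResult(params, aA, aB, trace, float(final_ll), converged, it, stats)
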