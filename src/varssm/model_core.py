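"""Core data model for the VAR state-space description of a gene regulatory network.

The hidden expression state evolves per grid sub-step as

    x_t = (I + A) x_{t-1} + B u_{t-1} + b + v_t,    v_t ~ N(0, diag(H))

where ``A`` holds per-sub-step regulatory effects among genes (the diagonal
encodes degradation, off-diagonal sign encodes activation/repression), ``B``
couples known exogenous biomolecule concentrations ``u`` (e.g. a drug) into
the system, and ``b`` holds synthesis-rate intercepts.  Observations are the
genes themselves with diagonal Gaussian noise ``R``; the initial state is
N(mu0, diag(Sigma0)).  The time-step factor of the discretized dynamics is
absorbed into ``A``, ``B`` and ``b``, so all of them are per-sub-step
quantities tied to a particular :class:`TimeGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GRNParameters",
    "TimeGrid",
    "TimeCourseDataset",
    "PenaltyConfig",
    "transition_mean",
    "steady_state",
]

_GRID_TOL = 1e-9


@dataclass
class GRNParameters:
    """All parameters of the network model.

    A : (N, N) gene-on-gene regulatory effects per sub-step (diagonal =
        degradation, never reported as an edge).
    B : (N, M) exogenous-input effects; M may be 0.
    b : (N,) synthesis-rate intercepts (dense).
    H : (N,) diagonal system-noise variances, >= 0.
    R : (N,) diagonal observation-noise variances, >= 0.
    mu0, Sigma0 : mean and diagonal variances of the initial state.
    """

    A: np.ndarray
    B: np.ndarray
    b: np.ndarray
    H: np.ndarray
    R: np.ndarray
    mu0: np.ndarray
    Sigma0: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be square, got {self.A.shape}")
        self.B = np.asarray(self.B, dtype=float).reshape(n, -1)
        for name in ("b", "H", "R", "mu0", "Sigma0"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if v.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {v.shape}")
            setattr(self, name, v)
        for name in ("H", "R", "Sigma0"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} entries must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.A.shape[0]

    @property
    def n_exo(self) -> int:
        return self.B.shape[1]

    @property
    def F(self) -> np.ndarray:
        """State transition matrix I + A."""
        return np.eye(self.n_genes) + self.A

    def copy(self) -> "GRNParameters":
        return GRNParameters(
            self.A.copy(), self.B.copy(), self.b.copy(), self.H.copy(),
            self.R.copy(), self.mu0.copy(), self.Sigma0.copy(),
        )

    @classmethod
    def zeros(cls, n_genes: int, n_exo: int = 0) -> "GRNParameters":
        return cls(
            A=np.zeros((n_genes, n_genes)),
            B=np.zeros((n_genes, n_exo)),
            b=np.zeros(n_genes),
            H=np.ones(n_genes),
            R=np.ones(n_genes),
            mu0=np.zeros(n_genes),
            Sigma0=np.ones(n_genes),
        )


def transition_mean(params: GRNParameters, x: np.ndarray, u: np.ndarray | None = None) -> np.ndarray:
    """One-sub-step conditional mean (I + A) x + B u + b."""
    x = np.asarray(x, dtype=float).reshape(-1)
    n = params.n_genes
    if x.shape != (n,):
        raise ValueError(f"state has shape {x.shape}, expected ({n},)")
    out = x + params.A @ x + params.b
    if params.n_exo:
        if u is None:
            raise ValueError(f"model has {params.n_exo} exogenous inputs but u is None")
        u = np.asarray(u, dtype=float).reshape(-1)
        if u.shape != (params.n_exo,):
            raise ValueError(f"u has shape {u.shape}, expected ({params.n_exo},)")
        out = out + params.B @ u
    return out


def steady_state(params: GRNParameters, u_const: np.ndarray | None = None) -> np.ndarray:
    """Fixed point x* of the noiseless dynamics: solves A x* + B u + b = 0.

    Raises ``np.linalg.LinAlgError`` when ``A`` is singular (the fixed point is
    then not unique or does not exist).
    """
    rhs = params.b.copy()
    if params.n_exo and u_const is not None:
        rhs = rhs + params.B @ np.asarray(u_const, dtype=float).reshape(-1)
    elif params.n_exo and u_const is None:
        pass  # drug absent: u = 0
    cond = np.linalg.cond(params.A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"A is singular or near-singular (cond={cond:.3g}); no unique steady state"
        )
    return np.linalg.solve(params.A, -rhs)


@dataclass(frozen=True)
class TimeGrid:
    """Simulation grid: all sub-step times, the observed subset, and sub-step count.

    ``t_all`` is a uniform grid with spacing ``min(diff(t_obs)) / k`` covering
    [t_obs[0], t_obs[-1]]; every observed time must fall on the grid, so every
    consecutive observed pair is bridged by an integer number of sub-steps.
    """

    t_all: np.ndarray
    t_obs: np.ndarray
    k: int

    @classmethod
    def from_observed(cls, t_obs: Sequence[float], k: int = 1) -> "TimeGrid":
        t_obs = np.asarray(sorted(set(float(t) for t in t_obs)), dtype=float)
        if t_obs.size < 2:
            raise ValueError("need at least two observed times")
        if k < 1:
            raise ValueError("k must be a positive integer")
        dt = float(np.min(np.diff(t_obs))) / k
        n_steps = (t_obs[-1] - t_obs[0]) / dt
        if abs(n_steps - round(n_steps)) > 1e-6:
            raise ValueError("observed span is not an integer number of sub-steps")
        t_all = t_obs[0] + dt * np.arange(int(round(n_steps)) + 1)
        grid = cls(t_all=t_all, t_obs=t_obs, k=int(k))
        grid.obs_indices()  # validates that observed times land on the grid
        return grid

    @property
    def dt(self) -> float:
        return float(self.t_all[1] - self.t_all[0])

    @property
    def n_times(self) -> int:
        return self.t_all.size

    def obs_indices(self) -> np.ndarray:
        """Grid index of each observed time."""
        idx = np.rint((self.t_obs - self.t_all[0]) / self.dt).astype(int)
        ok = (idx >= 0) & (idx < self.t_all.size)
        if not np.all(ok) or np.max(np.abs(self.t_all[idx[ok]] - self.t_obs[ok])) > 1e-6:
            raise ValueError("observed times do not all fall on the grid")
        return idx


@dataclass
class TimeCourseDataset:
    """Replicated observations at observed times plus exogenous concentrations.

    y maps observed time -> list of (N,) replicate vectors (replicate counts
    may differ across times).  Exogenous concentrations are stored as sampled
    series (u_times, u_values) and linearly interpolated onto any grid; M = 0
    when u_values is None.  ``truth`` optionally carries the generating
    directed gene->gene edge set for benchmarking, and ``truth_exo`` the
    exogenous-input target list.
    """

    genes: list[str]
    y: dict[float, list[np.ndarray]]
    u_times: np.ndarray | None = None
    u_values: np.ndarray | None = None
    truth: set[tuple[str, str]] | None = None
    truth_exo: set[tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        n = len(self.genes)
        clean: dict[float, list[np.ndarray]] = {}
        for t in sorted(self.y):
            reps = [np.asarray(r, dtype=float).reshape(-1) for r in self.y[t]]
            for r in reps:
                if r.shape != (n,):
                    raise ValueError(f"replicate at t={t} has shape {r.shape}, expected ({n},)")
                if not np.all(np.isfinite(r)):
                    raise ValueError(f"non-finite observation at t={t}")
            clean[float(t)] = reps
        self.y = clean
        if self.u_values is not None:
            self.u_times = np.asarray(self.u_times, dtype=float).reshape(-1)
            self.u_values = np.asarray(self.u_values, dtype=float).reshape(self.u_times.size, -1)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_exo(self) -> int:
        return 0 if self.u_values is None else self.u_values.shape[1]

    @property
    def t_obs(self) -> np.ndarray:
        return np.asarray(sorted(self.y), dtype=float)

    @property
    def n_obs_vectors(self) -> int:
        """Total number of replicate observation vectors (the BIC sample size)."""
        return sum(len(r) for r in self.y.values())

    def u_on_grid(self, grid: TimeGrid) -> np.ndarray:
        """(T, M) exogenous concentrations at every grid time (empty when M=0)."""
        if self.n_exo == 0:
            return np.zeros((grid.n_times, 0))
        cols = [np.interp(grid.t_all, self.u_times, self.u_values[:, m])
                for m in range(self.n_exo)]
        return np.column_stack(cols)

    def without_times(self, times: Sequence[float]) -> "TimeCourseDataset":
        """Copy with all replicates at the given observed times removed."""
        drop = {float(t) for t in times}
        missing = drop - set(self.y)
        if missing:
            raise ValueError(f"held-out times not observed: {sorted(missing)}")
        y = {t: [r.copy() for r in reps] for t, reps in self.y.items() if t not in drop}
        return TimeCourseDataset(self.genes, y, self.u_times, self.u_values,
                                 self.truth, self.truth_exo)

    def copy(self) -> "TimeCourseDataset":
        return TimeCourseDataset(
            self.genes,
            {t: [r.copy() for r in reps] for t, reps in self.y.items()},
            None if self.u_times is None else self.u_times.copy(),
            None if self.u_values is None else self.u_values.copy(),
            None if self.truth is None else set(self.truth),
            None if self.truth_exo is None else set(self.truth_exo),
        )


@dataclass
class PenaltyConfig:
    """Row-wise L1 penalty configuration.

    lambda_n : per-gene penalty levels >= 0.
    cA, cB : weight matrices in (0, 1]; weights < 1 mark known regulations and
        shrink the corresponding penalty (prior knowledge).
    candidate_A : per-row sets of allowed off-diagonal regulator indices; the
        diagonal of A is always allowed and never penalized (degradation).
    candidate_B : per-row sets of allowed exogenous-input indices.
    Coordinates outside the candidate sets are held at exactly zero.
    """

    lambda_n: np.ndarray
    cA: np.ndarray
    cB: np.ndarray
    candidate_A: list[set[int]]
    candidate_B: list[set[int]]

    def __post_init__(self) -> None:
        self.lambda_n = np.asarray(self.lambda_n, dtype=float).reshape(-1)
        n = self.lambda_n.size
        self.cA = np.asarray(self.cA, dtype=float).reshape(n, n)
        self.cB = np.asarray(self.cB, dtype=float).reshape(n, -1)
        if np.any(self.lambda_n < 0):
            raise ValueError("lambda_n must be nonnegative")
        for name, w in (("cA", self.cA), ("cB", self.cB)):
            if w.size and (np.any(w <= 0) or np.any(w > 1)):
                raise ValueError(f"{name} weights must lie in (0, 1]")
        self.candidate_A = [set(int(j) for j in s if int(j) != i)
                            for i, s in enumerate(self.candidate_A)]
        self.candidate_B = [set(int(j) for j in s) for s in self.candidate_B]

    @classmethod
    def default(cls, n_genes: int, n_exo: int = 0, lam: float = 0.0) -> "PenaltyConfig":
        """Full candidate sets, unit weights, uniform penalty level."""
        return cls(
            lambda_n=np.full(n_genes, float(lam)),
            cA=np.ones((n_genes, n_genes)),
            cB=np.ones((n_genes, n_exo)),
            candidate_A=[set(range(n_genes)) - {i} for i in range(n_genes)],
            candidate_B=[set(range(n_exo)) for _ in range(n_genes)],
        )

    def copy(self) -> "PenaltyConfig":
        return PenaltyConfig(
            self.lambda_n.copy(), self.cA.copy(), self.cB.copy(),
            [set(s) for s in self.candidate_A], [set(s) for s in self.candidate_B],
        )
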