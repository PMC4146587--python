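"""Synthetic drug-stimulated pathway generators for benchmarking.

Two generators mirror the benchmark designs the model is aimed at:

* a linear difference-equation pathway — genes synthesize, degrade and
  regulate each other linearly on a fine time grid, perturbed by a drug whose
  concentration follows a one-compartment model (exponential decay);
* a hill-function ODE pathway — the same topology, but each regulation acts
  through a saturating hill term, integrated by Euler-Maruyama at a fine
  fixed step.

Both start at the pre-drug steady state, add the drug at a given onset,
and emit replicated observations at non-uniform observed times with Gaussian
noise whose variance is proportional to the signal intensity (floored), the
noise structure typical of microarray time courses.  All randomness flows
from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model_core import GRNParameters, TimeCourseDataset, TimeGrid, steady_state

__all__ = [
    "RegulationEdge",
    "PathwaySpec",
    "NoiseModel",
    "DrugSchedule",
    "drug_concentration",
    "hill_effect",
    "simulate_linear_course",
    "simulate_hill_course",
    "default_pathway",
    "cascade_pathway",
    "DEFAULT_OBSERVED_TIMES",
    "RAT_MUSCLE_TIMES",
]

# 11 non-uniform observed times: dense dynamic phase, steady tail.
DEFAULT_OBSERVED_TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0)

# Observed-time preset of the rat skeletal-muscle corticosteroid experiment [h].
RAT_MUSCLE_TIMES = (0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0, 5.0, 5.5, 7.0, 8.0,
                    12.0, 18.0, 30.0, 48.0, 72.0)


@dataclass
class RegulationEdge:
    regulator: str
    target: str
    sign: int                  # +1 activation, -1 repression
    form: str = "linear"       # "linear" | "hill"
    strength: float = 0.5      # continuous-time rate scale
    hill_K: float = 1.0
    hill_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.form not in ("linear", "hill"):
            raise ValueError("form must be 'linear' or 'hill'")
        if self.hill_K <= 0:
            raise ValueError("hill_K must be positive")
        if self.hill_gamma < 1:
            raise ValueError("hill_gamma must be >= 1")


@dataclass
class PathwaySpec:
    """Topology and kinetic rates of a simulated pathway (continuous-time units)."""

    genes: list[str]
    edges: list[RegulationEdge]
    synthesis: dict[str, float]
    degradation: dict[str, float]
    drug_targets: list[tuple[str, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.genes)
        for e in self.edges:
            if e.regulator not in known or e.target not in known:
                raise ValueError(f"edge {e.regulator}->{e.target} references unknown gene")
        for g in self.genes:
            if self.degradation.get(g, 0.0) <= 0:
                raise ValueError(f"degradation rate of {g} must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def truth_edges(self) -> set[tuple[str, str]]:
        return {(e.regulator, e.target) for e in self.edges}


@dataclass
class NoiseModel:
    """Observation variance = max(rho * |signal|, floor); system noise is
    additive Gaussian with variance system_sd^2 * dt per sub-step."""

    rho: float = 0.02
    system_sd: float = 0.02
    floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.floor <= 0:
            raise ValueError("floor must be positive")


@dataclass
class DrugSchedule:
    """One-compartment drug input: C(t) = C0 exp(-kel (t - onset)) for t >= onset."""

    C0: float = 5.0
    kel: float = 0.3
    onset: float = 0.0

    def concentration(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = np.where(t >= self.onset,
                     self.C0 * np.exp(-self.kel * np.maximum(t - self.onset, 0.0)),
                     0.0)
        return c


def drug_concentration(C0: float, kel: float, t: float) -> float:
    """One-compartment kinetics C0 * exp(-kel * t)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return float(C0 * np.exp(-kel * t))


def hill_effect(x: float, strength: float, K: float, gamma: float, sign: int) -> float:
    """Saturating regulation: activation strength*x^g/(K^g+x^g), repression
    strength*K^g/(K^g+x^g).  Bounded in [0, strength], monotone in x."""
    if K <= 0:
        raise ValueError("K must be positive")
    x = max(float(x), 0.0)
    num = x ** gamma if sign > 0 else K ** gamma
    return float(strength) * num / (K ** gamma + x ** gamma)


def _linear_rates(spec: PathwaySpec):
    """Continuous-time (W - D, s, g): dx/dt = s + (W - D) x + g u."""
    n = spec.n_genes
    gi = {g: i for i, g in enumerate(spec.genes)}
    W = np.zeros((n, n))
    for e in spec.edges:
        W[gi[e.target], gi[e.regulator]] += e.sign * e.strength
    D = np.diag([spec.degradation[g] for g in spec.genes])
    s = np.array([spec.synthesis.get(g, 0.0) for g in spec.genes])
    g = np.zeros(n)
    for gene, sign, strength in spec.drug_targets:
        g[gi[gene]] += sign * strength
    return W - D, s, g


def params_from_spec(spec: PathwaySpec, dt: float,
                     noise: NoiseModel | None = None) -> GRNParameters:
    """Discretize the linear pathway at step dt into per-sub-step parameters."""
    noise = noise or NoiseModel()
    WD, s, g = _linear_rates(spec)
    n = spec.n_genes
    return GRNParameters(
        A=dt * WD, B=(dt * g).reshape(n, 1), b=dt * s,
        H=np.full(n, noise.system_sd ** 2 * dt),
        R=np.full(n, noise.floor),
        mu0=np.zeros(n), Sigma0=np.full(n, 1e-6),
    )


def _observe(x_at_obs: np.ndarray, t_obs: np.ndarray, genes, replicates: int,
             noise: NoiseModel, rng) -> dict[float, list[np.ndarray]]:
    y: dict[float, list[np.ndarray]] = {}
    for j, t in enumerate(t_obs):
        sd = np.sqrt(np.maximum(noise.rho * np.abs(x_at_obs[j]), noise.floor))
        y[float(t)] = [x_at_obs[j] + rng.normal(0.0, sd) for _ in range(replicates)]
    return y


def simulate_linear_course(spec: PathwaySpec, grid: TimeGrid,
                           drug: DrugSchedule | None = None,
                           noise: NoiseModel | None = None,
                           replicates: int = 3, seed: int = 0) -> TimeCourseDataset:
    """Linear difference-equation course on the grid's sub-steps.

    The state starts at the pre-drug steady state, evolves by
    x_t = x_{t-1} + dt*(W - D) x_{t-1} + dt*g u_{t-1} + dt*s + system noise,
    and is observed with intensity-proportional noise at the observed times.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    noise = noise or NoiseModel()
    drug = drug or DrugSchedule()
    rng = np.random.default_rng(seed)
    params = params_from_spec(spec, grid.dt, noise)
    x = steady_state(params, u_const=None)  # pre-drug equilibrium
    u = drug.concentration(grid.t_all).reshape(-1, 1)
    T = grid.n_times
    n = spec.n_genes
    sd_sys = noise.system_sd * np.sqrt(grid.dt)
    X = np.empty((T, n))
    X[0] = x
    F = params.F
    for t in range(1, T):
        X[t] = (F @ X[t - 1] + params.B[:, 0] * u[t - 1, 0] + params.b
                + rng.normal(0.0, sd_sys, size=n))
        if np.max(np.abs(X[t])) > 1e6:
            rad = float(np.max(np.abs(np.linalg.eigvals(F))))
            raise RuntimeError(
                f"simulated dynamics diverged (spectral radius of I+A = {rad:.4f})")
    obs_idx = grid.obs_indices()
    y = _observe(X[obs_idx], grid.t_obs, spec.genes, replicates, noise, rng)
    gi = {g: i for i, g in enumerate(spec.genes)}
    return TimeCourseDataset(
        genes=list(spec.genes), y=y, u_times=grid.t_all.copy(), u_values=u,
        truth=spec.truth_edges(),
        truth_exo={(0, g) for g, _, _ in spec.drug_targets},
    )


def _hill_rhs(spec: PathwaySpec, gi: dict[str, int], x: np.ndarray,
              u: float, g: np.ndarray) -> np.ndarray:
    n = spec.n_genes
    dx = np.array([spec.synthesis.get(gn, 0.0) for gn in spec.genes])
    for e in spec.edges:
        xr = x[gi[e.regulator]]
        if e.form == "hill":
            dx[gi[e.target]] += hill_effect(xr, e.strength, e.hill_K,
                                            e.hill_gamma, e.sign)
        else:
            dx[gi[e.target]] += e.sign * e.strength * max(xr, 0.0)
    dx += g * u
    dx -= np.array([spec.degradation[gn] for gn in spec.genes]) * x
    return dx


def simulate_hill_course(spec: PathwaySpec, times,
                         drug: DrugSchedule | None = None,
                         noise: NoiseModel | None = None,
                         replicates: int = 3, seed: int = 0,
                         step_factor: float = 1e-2) -> TimeCourseDataset:
    """Hill-function ODE course: Euler-Maruyama at a fixed fine step.

    ``times`` are the observed times; the integrator step is
    step_factor * (minimal observed spacing).  Initialization is the pre-drug
    equilibrium (numerical root of the drift).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    noise = noise or NoiseModel()
    drug = drug or DrugSchedule()
    rng = np.random.default_rng(seed)
    t_obs = np.asarray(sorted(float(t) for t in times))
    gi = {g: i for i, g in enumerate(spec.genes)}
    _, s, gvec = _linear_rates(spec)
    deg = np.array([spec.degradation[g] for g in spec.genes])
    x0_guess = np.array([spec.synthesis.get(g, 0.0) for g in spec.genes]) / deg

    def drift0(x):
        return _hill_rhs(spec, gi, x, 0.0, gvec)

    x0, info, ier, _ = optimize.fsolve(drift0, x0_guess, full_output=True)
    if ier != 1 or np.max(np.abs(drift0(x0))) > 1e-8:
        raise RuntimeError("could not locate the pre-drug equilibrium")

    h = step_factor * float(np.min(np.diff(t_obs)))
    n_steps = int(np.ceil((t_obs[-1] - t_obs[0]) / h))
    h = (t_obs[-1] - t_obs[0]) / n_steps
    t_grid = t_obs[0] + h * np.arange(n_steps + 1)
    u_grid = drug.concentration(t_grid)
    sd = noise.system_sd * np.sqrt(h)
    x = x0.copy()
    traj = np.empty((n_steps + 1, spec.n_genes))
    traj[0] = x
    for i in range(n_steps):
        x = x + h * _hill_rhs(spec, gi, x, u_grid[i], gvec) \
            + rng.normal(0.0, sd, size=spec.n_genes)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6:
            raise RuntimeError(f"ODE integration blew up at t={t_grid[i+1]:.4g}")
        traj[i + 1] = x
    obs_idx = np.rint((t_obs - t_obs[0]) / h).astype(int)
    y = _observe(traj[obs_idx], t_obs, spec.genes, replicates, noise, rng)
    return TimeCourseDataset(
        genes=list(spec.genes), y=y, u_times=t_grid, u_values=u_grid.reshape(-1, 1),
        truth=spec.truth_edges(),
        truth_exo={(0, g) for g, _, _ in spec.drug_targets},
    )


def cascade_pathway() -> PathwaySpec:
    """Small fixed benchmark: a 5-gene drug-stimulated cascade.

    drug -> g1 -> g2 -> {g3 -> g4 (repression), g5}; heterogeneous synthesis,
    degradation and baselines give each gene a distinct time constant.
    """
    genes = ["g1", "g2", "g3", "g4", "g5"]
    edges = [RegulationEdge("g1", "g2", 1, "linear", 0.9),
             RegulationEdge("g2", "g3", 1, "linear", 0.8),
             RegulationEdge("g3", "g4", -1, "linear", 0.7),
             RegulationEdge("g2", "g5", 1, "linear", 1.0)]
    deg = dict(zip(genes, [0.9, 0.35, 0.6, 1.0, 0.45]))
    base = dict(zip(genes, [2.0, 1.5, 2.5, 2.0, 3.0]))
    contrib = {g: 0.0 for g in genes}
    for e in edges:
        contrib[e.target] += e.sign * e.strength * base[e.regulator]
    # scale oversupplied incoming strengths so the baselines are exact equilibria
    for g in genes:
        cap = deg[g] * base[g] - 0.05
        if contrib[g] > cap:
            f = cap / contrib[g]
            for e in edges:
                if e.target == g:
                    e.strength *= f
            contrib[g] = cap
    syn = {g: deg[g] * base[g] - contrib[g] for g in genes}
    return PathwaySpec(genes, edges, syn, deg, drug_targets=[("g1", 1, 0.6)])


def default_pathway(n_genes: int = 18, seed: int = 0, hill: bool = False) -> PathwaySpec:
    """Drug-stimulated scaffold: drug hits 3 root genes, cascades with mixed
    signs fan out to the rest; 22 gene-gene edges at the default 18 genes.

    Deterministic per seed.  With ``hill=True`` roughly half the edges act
    through hill terms with half-saturation at the regulator's baseline.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i+1:02d}" for i in range(n_genes)]
    roots = genes[:3]
    edges: list[RegulationEdge] = []
    seen: set[tuple[str, str]] = set()

    baseline = rng.uniform(1.5, 3.0, size=n_genes)
    # fast turnover keeps regulation strong at equilibrium and responses crisp
    deg = rng.uniform(0.4, 1.6, size=n_genes)

    def add_edge(i: int, j: int) -> None:  # gene i regulates gene j
        sign = 1 if rng.random() < 0.7 else -1
        strength = rng.uniform(0.7, 1.2)
        form = "hill" if (hill and rng.random() < 0.5) else "linear"
        K = baseline[i]
        e = RegulationEdge(genes[i], genes[j], sign, form,
                           strength if form == "linear" else 2.0 * strength * baseline[i],
                           hill_K=K, hill_gamma=float(rng.choice([1.0, 2.0])))
        edges.append(e)
        seen.add((genes[i], genes[j]))

    # shallow spanning cascade: parents drawn from early (root-near) genes so
    # the drug response does not attenuate down long chains
    for j in range(3, n_genes):
        add_edge(int(rng.integers(0, min(j, 8))), j)
    # extra cross edges (22 total at n=18), last one fed back to a root
    n_extra = int(round(7 * (n_genes - 3) / 15))
    tries = 0
    while n_extra > 0 and tries < 1000:
        tries += 1
        if n_extra == 1:
            i, j = int(rng.integers(3, n_genes)), int(rng.integers(0, 3))
        else:
            i = int(rng.integers(0, n_genes - 1))
            j = int(rng.integers(i + 1, n_genes))
        if i == j or (genes[i], genes[j]) in seen:
            continue
        add_edge(i, j)
        n_extra -= 1

    # synthesis rates chosen so the chosen baselines are exact pre-drug
    # equilibria; where regulation alone would oversupply a gene, its incoming
    # strengths are scaled down instead of clamping synthesis (a clamp would
    # shift the equilibria away from the designed baselines)
    gidx = {g: i for i, g in enumerate(genes)}

    def edge_contrib(e: RegulationEdge) -> float:
        xr = baseline[gidx[e.regulator]]
        if e.form == "hill":
            return hill_effect(xr, e.strength, e.hill_K, e.hill_gamma, e.sign)
        return e.sign * e.strength * xr

    contrib = np.zeros(n_genes)
    for e in edges:
        contrib[gidx[e.target]] += edge_contrib(e)
    for j in range(n_genes):
        cap = deg[j] * baseline[j] - 0.05
        if contrib[j] > cap:
            f = cap / contrib[j]
            for e in edges:
                if gidx[e.target] == j:
                    e.strength *= f
            contrib[j] = cap
    synthesis = deg * baseline - contrib

    drug_targets = [(roots[0], 1, float(rng.uniform(1.0, 1.8))),
                    (roots[1], 1, float(rng.uniform(1.0, 1.8))),
                    (roots[2], -1, float(rng.uniform(0.4, 0.7)))]
    return PathwaySpec(
        genes=genes, edges=edges,
        synthesis={g: float(s) for g, s in zip(genes, synthesis)},
        degradation={g: float(d) for g, d in zip(genes, deg)},
        drug_targets=drug_targets,
    )
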