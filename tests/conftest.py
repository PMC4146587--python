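import numpy as np
import pytest

import varssm as v


def random_params(n: int, m: int, rng, stable: bool = True) -> v.GRNParameters:
    A = rng.normal(0, 0.15, (n, n)) - 0.4 * np.eye(n)
    if stable:
        # keep |eig(I+A)| < 1 so oracle covariances stay well scaled
        ev = np.max(np.abs(np.linalg.eigvals(np.eye(n) + A)))
        if ev >= 0.95:
            A *= 0.9 / ev
    return v.GRNParameters(
        A=A,
        B=rng.normal(0, 0.3, (n, m)),
        b=rng.normal(0, 0.5, n),
        H=rng.uniform(0.05, 0.2, n),
        R=rng.uniform(0.05, 0.2, n),
        mu0=rng.normal(0, 1, n),
        Sigma0=rng.uniform(0.5, 1.5, n),
    )


def random_dataset(n: int, m: int, grid: v.TimeGrid, rng,
                   reps=(2, 1, 2)) -> v.TimeCourseDataset:
    y = {}
    for t, r in zip(grid.t_obs, reps):
        y[float(t)] = [rng.normal(0, 1, n) for _ in range(r)]
    u_t = u_v = None
    if m:
        u_t = grid.t_all.copy()
        u_v = rng.uniform(0, 2, (u_t.size, m))
    return v.TimeCourseDataset(genes=[f"g{i}" for i in range(n)], y=y,
                               u_times=u_t, u_values=u_v)


@pytest.fixture(scope="session")
def tiny_grid():
    """3 observed times bridged by 2 sub-steps each (5 grid points)."""
    return v.TimeGrid.from_observed([0.0, 1.0, 2.0], k=2)


@pytest.fixture(scope="session")
def obs_grid():
    """The default non-uniform 11-point observation design."""
    return v.TimeGrid.from_observed(v.DEFAULT_OBSERVED_TIMES, k=1)


@pytest.fixture(scope="session")
def cascade_data(obs_grid):
    """Deterministic 5-gene drug-stimulated cascade with 1% intensity noise."""
    spec = v.cascade_pathway()
    noise = v.NoiseModel(rho=0.005, system_sd=0.0, floor=1e-6)
    return v.simulate_linear_course(spec, obs_grid, v.DrugSchedule(C0=5, kel=0.3),
                                    noise, replicates=3, seed=11)
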