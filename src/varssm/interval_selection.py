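"""Choice of the simulation sub-step count via BIC and held-out prediction error.

The hidden-state grid places ``k`` sub-steps inside the minimal observed
spacing.  For each candidate ``k`` the structure search is run and two scores
are recorded: the global BIC, and the sum of squared prediction errors (SPE)
at a small set of held-out observed times.  For each held-out time the model
is refit without the replicates at that time — by default only the parameter
values are re-optimized with the selected active sets held fixed; a full
structure re-search is available via ``SearchConfig.spe_refit_structure`` —
and the observation there is predicted by propagating the filtered state
forward.  Held-out times should lie in the dynamic phase: errors at
steady-state points carry no information about the step size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .em import em_fit, _as_courses
from .kalman import kalman_filter
from .model_core import PenaltyConfig, TimeGrid
from .structure_search import NetworkEstimate, SearchConfig, search

__all__ = ["IntervalScan", "ScanEntry", "spe", "scan_substeps", "default_heldout_times"]

logger = logging.getLogger(__name__)


@dataclass
class ScanEntry:
    k: int
    estimate: NetworkEstimate
    bic: float
    spe: float


@dataclass
class IntervalScan:
    entries: list[ScanEntry]
    k_best_bic: int
    k_best_spe: int


def default_heldout_times(t_obs) -> list[float]:
    """The three earliest non-initial observed times (the dynamic phase)."""
    t = sorted(float(x) for x in t_obs)
    return t[1:4]


def _steady_state_warning(courses, heldout_times) -> None:
    for c in courses:
        t_last = max(c.y)
        y_last = np.mean(np.vstack(c.y[t_last]), axis=0)
        scale = max(float(np.max(np.abs(y_last))), 1e-12)
        for tau in heldout_times:
            if float(tau) == t_last or float(tau) not in c.y:
                continue
            y_tau = np.mean(np.vstack(c.y[float(tau)]), axis=0)
            if np.max(np.abs(y_tau - y_last)) / scale < 0.01:
                warnings.warn(
                    f"held-out time {tau} is within 1% of the final observation; "
                    "steady-state points cannot discriminate the time interval",
                    UserWarning, stacklevel=3)


def spe(data, grid: TimeGrid, heldout_times, penalty: PenaltyConfig | None = None,
        config: SearchConfig | None = None,
        estimate: NetworkEstimate | None = None) -> float:
    """Sum of squared one-step prediction errors at held-out observed times.

    For each held-out time the model is refit on the data without the
    replicates at that time, the filtered state before the time is propagated
    to it, and the squared error against the withheld replicates is summed
    over genes and replicates (and over courses).
    """
    config = config or SearchConfig()
    courses = _as_courses(data)
    heldout_times = [float(t) for t in heldout_times]
    for tau in heldout_times:
        for c in courses:
            if tau not in c.y or not c.y[tau]:
                raise ValueError(f"held-out time {tau} has no observation")
    _steady_state_warning(courses, heldout_times)
    if estimate is None and not config.spe_refit_structure:
        estimate = search(courses, grid, penalty, config)

    obs_idx = {float(t): i for t, i in zip(grid.t_obs, grid.obs_indices())}
    total = 0.0
    for tau in heldout_times:
        reduced = [c.without_times([tau]) for c in courses]
        if config.spe_refit_structure:
            est_tau = search(reduced, grid, penalty, config)
            params_tau = est_tau.params
        else:
            pen = (penalty.copy() if penalty is not None
                   else PenaltyConfig.default(courses[0].n_genes, courses[0].n_exo))
            pen.lambda_n[:] = 0.0
            for i in range(courses[0].n_genes):
                pen.candidate_A[i] = set(estimate.active_A[i])
                pen.candidate_B[i] = set(estimate.active_B[i])
            fit = em_fit(reduced, grid, pen, init=estimate.params,
                         tol=config.em_tol, max_iter=config.em_max_iter)
            params_tau = fit.params
        ti = obs_idx[tau]
        for full, red in zip(courses, reduced):
            filt = kalman_filter(params_tau, red, grid)
            pred = filt.pred_mean[ti] if ti > 0 else params_tau.mu0
            for y in full.y[tau]:
                total += float(np.sum((y - pred) ** 2))
    return total


def scan_substeps(data, k_values, heldout_times=None,
                  penalty_weights: PenaltyConfig | None = None,
                  config: SearchConfig | None = None) -> IntervalScan:
    """Run the structure search and SPE for each sub-step count and pick minima."""
    config = config or SearchConfig()
    courses = _as_courses(data)
    k_values = [int(k) for k in k_values]
    if not k_values:
        raise ValueError("k_values must be non-empty")
    if len(set(k_values)) != len(k_values):
        raise ValueError("k_values must be distinct")
    t_obs = courses[0].t_obs
    if heldout_times is None:
        heldout_times = default_heldout_times(t_obs)
    entries: list[ScanEntry] = []
    for k in k_values:
        grid = TimeGrid.from_observed(t_obs, k)
        est = search(courses, grid, penalty_weights, config)
        s = spe(courses, grid, heldout_times, penalty_weights, config, estimate=est)
        logger.info("k=%d: bic=%.4f spe=%.6g (%d edges)", k, est.bic, s, len(est.edges))
        entries.append(ScanEntry(k, est, est.bic, s))
    k_best_bic = entries[int(np.argmin([e.bic for e in entries]))].k
    k_best_spe = entries[int(np.argmin([e.spe for e in entries]))].k
    return IntervalScan(entries, k_best_bic, k_best_spe)
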