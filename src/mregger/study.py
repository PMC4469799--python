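"""Monte Carlo performance study for the IVW and MR-Egger estimators.

Sweeps pleiotropy scenario x causal effect x sample size x variant count,
simulating two-sample summary datasets and tabulating, per cell: the mean F
statistic (instrument strength), mean causal-effect estimates and standard
errors for both estimators, the two-sided rejection rates of the causal null
at a nominal level, and the rejection rate of the MR-Egger intercept test
(power to detect directional pleiotropy).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, replace
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import orient
from .estimators import ivw, mean_f_statistic, mr_egger
from .simulate import ScenarioSpec, SimulationParams, simulate_summary_dataset

__all__ = ["PerformanceRow", "run_cell", "run_grid", "cell_seed"]

logger = logging.getLogger(__name__)

#: replicates whose simulated data are degenerate (e.g. a monomorphic
#: variant) are redrawn with a fresh sub-seed at most this many times each
MAX_RETRIES = 10


@dataclass(frozen=True)
class PerformanceRow:
    """One cell of the simulation study."""

    scenario: str
    beta: float
    n_per_sample: int
    n_variants: int
    n_reps: int
    alpha_level: float
    mean_f: float
    ivw_mean_estimate: float
    ivw_mean_se: float
    ivw_rejection_rate: float
    egger_mean_estimate: float
    egger_mean_se: float
    egger_rejection_rate: float
    egger_intercept_rejection_rate: float
    n_retries: int = 0

    def __post_init__(self) -> None:
        for name in (
            "ivw_rejection_rate",
            "egger_rejection_rate",
            "egger_intercept_rejection_rate",
        ):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {rate}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.mean_f < 0:
            raise ValueError("mean_f must be non-negative")


def run_cell(
    params: SimulationParams,
    n_reps: int,
    alpha_level: float = 0.05,
    se_model: str = "regression-output",
) -> PerformanceRow:
    """Simulate ``n_reps`` replicate datasets under ``params`` and aggregate.

    Each replicate: simulate the two cohorts, summarize, orient, fit IVW and
    MR-Egger, and record the estimates, their standard errors and the
    two-sided t-test decisions at ``alpha_level`` for (i) causal slope = 0
    under each method and (ii) MR-Egger intercept = 0.  Degenerate replicates
    are redrawn from a fresh sub-seed and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0.0 < alpha_level <= 1.0):
        raise ValueError("alpha_level must lie in (0, 1]")

    ivw_est = np.empty(n_reps)
    ivw_se = np.empty(n_reps)
    ivw_rej = np.empty(n_reps, dtype=bool)
    egg_est = np.empty(n_reps)
    egg_se = np.empty(n_reps)
    egg_rej = np.empty(n_reps, dtype=bool)
    egg_int_rej = np.empty(n_reps, dtype=bool)
    mean_fs = np.empty(n_reps)
    n_retries = 0

    for rep in range(n_reps):
        for attempt in range(MAX_RETRIES + 1):
            seed_seq = np.random.SeedSequence((params.seed, rep, attempt))
            try:
                dataset, _ = simulate_summary_dataset(params, seed_seq)
                dataset = orient(dataset)
                fit_ivw = ivw(dataset, se_model=se_model)
                fit_egger = mr_egger(dataset, se_model=se_model)
                break
            except ValueError as err:
                n_retries += 1
                logger.debug("replicate %d attempt %d degenerate: %s", rep, attempt, err)
        else:
            raise RuntimeError(
                f"replicate {rep} degenerate after {MAX_RETRIES} retries"
            )
        mean_fs[rep] = mean_f_statistic(dataset)
        ivw_est[rep] = fit_ivw.slope
        ivw_se[rep] = fit_ivw.slope_se
        ivw_rej[rep] = fit_ivw.slope_p <= alpha_level
        egg_est[rep] = fit_egger.slope
        egg_se[rep] = fit_egger.slope_se
        egg_rej[rep] = fit_egger.slope_p <= alpha_level
        egg_int_rej[rep] = fit_egger.intercept_p <= alpha_level

    return PerformanceRow(
        scenario=params.scenario.label,
        beta=params.beta,
        n_per_sample=params.n_per_sample,
        n_variants=params.n_variants,
        n_reps=n_reps,
        alpha_level=alpha_level,
        mean_f=float(mean_fs.mean()),
        ivw_mean_estimate=float(ivw_est.mean()),
        ivw_mean_se=float(ivw_se.mean()),
        ivw_rejection_rate=float(ivw_rej.mean()),
        egger_mean_estimate=float(egg_est.mean()),
        egger_mean_se=float(egg_se.mean()),
        egger_rejection_rate=float(egg_rej.mean()),
        egger_intercept_rejection_rate=float(egg_int_rej.mean()),
        n_retries=n_retries,
    )


def cell_seed(master_seed: int, scenario: str, beta: float, n: int, j: int) -> int:
    """Stable, order-independent seed for one grid cell (< 2**31)."""
    key = f"{master_seed}|{scenario}|{beta!r}|{n}|{j}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % 2**31


def run_grid(
    scenarios: Iterable[str],
    betas: Sequence[float],
    sample_sizes: Sequence[int],
    variant_counts: Sequence[int],
    n_reps: int,
    seed: int,
    alpha_level: float = 0.05,
    base_params: SimulationParams | None = None,
) -> pd.DataFrame:
    """Run every cell of the scenario grid and return a tidy table.

    Each cell's seed is a stable hash of (seed, scenario, beta, N, J), so
    results are independent of the order in which cells are listed or run.
    ``base_params`` carries the non-grid parameters (gamma scale, pleiotropy
    scale, MAF law); its own scenario/beta/N/J/seed fields are overridden
    cell by cell.
    """
    scenarios = list(scenarios)
    if not (scenarios and betas and sample_sizes and variant_counts):
        raise ValueError("all grid dimensions must be non-empty")
    if base_params is None:
        base_params = SimulationParams(n_per_sample=sample_sizes[0])
    rows = []
    for label, beta, n, j in product(scenarios, betas, sample_sizes, variant_counts):
        params = replace(
            base_params,
            scenario=ScenarioSpec.from_label(label),
            beta=beta,
            n_per_sample=n,
            n_variants=j,
            seed=cell_seed(seed, label, beta, n, j),
        )
        logger.info("cell scenario=%s beta=%g N=%d J=%d", label, beta, n, j)
        rows.append(asdict(run_cell(params, n_reps, alpha_level)))
    return pd.DataFrame(rows)
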