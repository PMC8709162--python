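"""Factorial simulation study: generate, sample, fit, score.

One *cell* fixes the data-generating conditions — network size and degree,
self-weight target, number of fitted time steps, scale precision, recruitment
probability, adjacency variety, and the bounded-confidence/decay parameters.
Each replicate of a cell generates a fresh ground truth (rejecting
disconnected networks and samples of fewer than four agents), snowball
samples it, fits the DeGroot model to the sampled ordinal panel with the
genetic algorithm, and scores the fit with the four RMSE metrics.

Seeds are derived from the master seed by hashing the cell's field tuple and
the replicate index, so results do not depend on execution order or worker
count.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .dynamics import DynamicsSpec
from .fit import GAConfig, ga_fit, modeled_trajectory
from .metrics import (
    EvaluationContext,
    modeling_rmse,
    ordinal_fit_rmse,
    prediction_rmse,
    recovery_rmse,
)
from .panel import ObservedPanel
from .sampling import (
    ADJACENCY_KINDS,
    GenerationError,
    build_adjacency_variety,
    sample_with_rejection,
)
from .scale import OrdinalScale

__all__ = [
    "SimCell",
    "MetricsRecord",
    "RESULT_COLUMNS",
    "FULL_GRID",
    "REDUCED_GRID",
    "cell_seed",
    "expand_grid",
    "run_cell",
    "run_grid",
]

logger = logging.getLogger(__name__)

N_SIM_STEPS = 20  # trajectories span t = 0..20

RESULT_COLUMNS = [
    "N", "d", "self_weight", "T", "n", "p", "adjacency", "delta", "lambda",
    "replicate", "cell_seed", "M", "recovery_rmse", "modeling_rmse",
    "prediction_rmse", "ordinal_fit_rmse", "objective", "generations",
]

# The factorial design of the full study.
FULL_GRID = {
    "N": [10, 20, 50],
    "d": [5, 9],
    "target_self_weight": [0.5],
    "T": [2, 3, 6],
    "n": [5, 7, 10, 20, 30],
    "p": [0.5, 1.0],
    "adjacency_kind": list(ADJACENCY_KINDS),
    "delta": [0.1, 0.5, 0.9, 1.0],
    "lam": [0.1, 0.5, 0.9, 1.0],
}

# A small documented default for interactive use; the full factorial crosses
# 14,400 cells and is run with --full-grid.
REDUCED_GRID = {
    "N": [10],
    "d": [5],
    "target_self_weight": [0.5],
    "T": [2, 6],
    "n": [5, 30],
    "p": [0.5],
    "adjacency_kind": ["build", "remove"],
    "delta": [1.0],
    "lam": [1.0],
}


@dataclass(frozen=True)
class SimCell:
    """One combination of simulation-study inputs."""

    N: int = 10
    d: int = 5
    target_self_weight: float = 0.5
    T: int = 6
    n: int = 30
    p: float = 0.5
    adjacency_kind: str = "remove"
    delta: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.adjacency_kind not in ADJACENCY_KINDS:
            raise ValueError(f"unknown adjacency kind {self.adjacency_kind!r}")
        if not (2 <= self.T <= N_SIM_STEPS):
            raise ValueError(f"T must lie in 2..{N_SIM_STEPS}")
        DynamicsSpec(self.delta, self.lam)  # validates ranges

    @property
    def spec(self) -> DynamicsSpec:
        return DynamicsSpec(self.delta, self.lam)


@dataclass
class MetricsRecord:
    """Flat result row for one (cell, replicate)."""

    cell: SimCell
    replicate: int
    cell_seed: int
    M: int
    recovery_rmse: float
    modeling_rmse: float
    prediction_rmse: float
    ordinal_fit_rmse: float
    objective: float
    generations: int

    def to_row(self) -> dict:
        c = self.cell
        return {
            "N": c.N, "d": c.d, "self_weight": c.target_self_weight,
            "T": c.T, "n": c.n, "p": c.p, "adjacency": c.adjacency_kind,
            "delta": c.delta, "lambda": c.lam, "replicate": self.replicate,
            "cell_seed": self.cell_seed, "M": self.M,
            "recovery_rmse": self.recovery_rmse,
            "modeling_rmse": self.modeling_rmse,
            "prediction_rmse": self.prediction_rmse,
            "ordinal_fit_rmse": self.ordinal_fit_rmse,
            "objective": self.objective, "generations": self.generations,
        }


def cell_seed(master_seed: int, cell: SimCell, replicate: int) -> int:
    """Deterministic per-replicate seed from the cell's content.

    Hashing the field tuple (rather than a position counter) makes results
    invariant to grid ordering and parallel scheduling.
    """
    key = repr((int(master_seed), tuple(sorted(asdict(cell).items())), int(replicate)))
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def expand_grid(grid: dict) -> list[SimCell]:
    """Cross a {field: values} mapping into a list of cells."""
    fields = list(grid)
    cells = [
        SimCell(**dict(zip(fields, combo)))
        for combo in itertools.product(*(grid[f] for f in fields))
    ]
    if not cells:
        raise ValueError("empty simulation grid")
    return cells


def run_cell(
    cell: SimCell,
    replicate: int = 0,
    master_seed: int = 0,
    ga_config: GAConfig | None = None,
    max_tries: int = 1000,
) -> MetricsRecord:
    """Run one replicate of one cell end to end.

    Generates truth and trajectory under the cell's dynamics, back-transforms
    all opinions to the n-point scale, snowball-samples, builds the requested
    adjacency variety, fits on the sampled agents' ordinal opinions for
    t = 0..T-1, and scores the fit.  Build runs are scored against the
    correct matrix.  Failed generation (budget exhausted) yields a record
    with NaN metrics and M = 0.
    """
    seed = cell_seed(master_seed, cell, replicate)
    rng = np.random.default_rng(seed)
    scale = OrdinalScale(cell.n)
    base = GAConfig() if ga_config is None else ga_config
    config = replace(base, rng_seed=int(rng.integers(2**31)))
    try:
        truth, sample, _ = sample_with_rejection(
            cell.N, cell.d, cell.p, rng,
            target_self_weight=cell.target_self_weight,
            spec=cell.spec, n_steps=N_SIM_STEPS, max_tries=max_tries,
        )
    except GenerationError:
        logger.warning("cell %s replicate %d: generation failed", cell, replicate)
        return MetricsRecord(
            cell, replicate, seed, 0,
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), 0,
        )
    ids = list(sample.sampled_ids)
    variety = build_adjacency_variety(truth.adjacency, sample, cell.adjacency_kind, rng)
    ordinal_all = scale.back(truth.trajectory)
    panel = ObservedPanel(
        ordinal_opinions=ordinal_all[np.ix_(ids, range(cell.T))],
        observed_steps=tuple(range(cell.T)),
        scale=scale,
        adjacency=variety,
        agent_ids=tuple(ids),
    )
    fit = ga_fit(panel, config)
    modeled = modeled_trajectory(fit.weights, panel, n_steps=N_SIM_STEPS)
    if cell.adjacency_kind == "build":
        eval_adj = build_adjacency_variety(truth.adjacency, sample, "correct")
    else:
        eval_adj = variety
    ctx = EvaluationContext(
        true_weights_reduced=truth.weights[np.ix_(ids, ids)],
        estimated_weights=fit.weights,
        eval_adjacency=eval_adj,
        latent_trajectory=truth.trajectory[ids],
        modeled_trajectory=modeled,
        T=cell.T,
        scale=scale,
    )
    return MetricsRecord(
        cell, replicate, seed, sample.size,
        recovery_rmse(ctx), modeling_rmse(ctx), prediction_rmse(ctx),
        ordinal_fit_rmse(ctx), fit.objective_value, fit.generations_run,
    )


def run_grid(
    cells,
    replicates: int = 10,
    master_seed: int = 0,
    ga_config: GAConfig | None = None,
    n_workers: int = 1,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Run every (cell, replicate) pair and return a tidy results table.

    Per-replicate seeds depend only on cell content, so the output is
    identical for any worker count or cell ordering (after sorting rows).
    """
    cells = list(cells)
    if not cells:
        raise ValueError("empty simulation grid")
    jobs = [(c, r) for c in cells for r in range(replicates)]
    if n_workers > 1:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            records = list(
                pool.map(
                    _run_job,
                    [(c, r, master_seed, ga_config, max_tries) for c, r in jobs],
                    chunksize=4,
                )
            )
    else:
        records = [
            run_cell(c, r, master_seed, ga_config, max_tries) for c, r in jobs
        ]
    df = pd.DataFrame([rec.to_row() for rec in records], columns=RESULT_COLUMNS)
    return df


def _run_job(args) -> MetricsRecord:
    cell, replicate, master_seed, ga_config, max_tries = args
    return run_cell(cell, replicate, master_seed, ga_config, max_tries)
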