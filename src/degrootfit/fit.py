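"""Genetic-algorithm estimation of the influence-weight matrix.

The search space is the set of row-stochastic matrices conforming to the
structural zeros of a given adjacency matrix.  A chromosome is a whole
candidate weight matrix; a gene is one of its rows — the influence profile
on one agent.  Fitness is a bin-penalised objective: deviation between
modeled and observed opinions on the continuous scale counts only when the
two also disagree on the ordinal scale, weighted by how many bins apart they
are.  The objective is therefore exactly zero when every modeled opinion
back-transforms to its observed level at every observed non-initial step.

Every operator — blending (per-gene convex combination), crossover (gene
exchange), mutation (masked Gaussian perturbation with renormalisation) —
maps feasible chromosomes to feasible chromosomes, so no repair step is
needed and the population is feasible in every generation.

Only plain DeGroot dynamics are fitted.  When the generating process
involves bounded confidence or decay the fit is deliberately misspecified;
the extensions' parameters are not estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import validate_adjacency
from .panel import ObservedPanel

__all__ = [
    "GAConfig",
    "FitResult",
    "modeled_trajectory",
    "objective",
    "objective_by_agent",
    "row_objective",
    "random_chromosome",
    "ga_fit",
    "average_fits",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    population_size : chromosomes per generation.
    n_generations : evolution budget (early stop on a perfect fit).
    selection_size : tournament size for parent selection.
    blend_rate : probability an offspring blends each gene with its second
        parent through a per-gene convex combination.
    crossover_rate : probability an offspring exchanges genes (rows) with
        its second parent (each gene swapped with probability 1/2).
    mutation_rate : per-gene probability of a Gaussian perturbation.
    mutation_magnitude : standard deviation of the perturbation before
        clipping at zero and renormalising the row.
    elite_count : best chromosomes copied unchanged into the next generation.
    rng_seed : seed for the search's own randomness.
    tolerance : stop once the best objective is at or below this (0 stops
        only on a perfect fit; a negative value disables early stopping).
    """

    population_size: int = 100
    n_generations: int = 3000
    selection_size: int = 2
    blend_rate: float = 0.4
    crossover_rate: float = 0.4
    mutation_rate: float = 0.2
    mutation_magnitude: float = 0.1
    elite_count: int = 1
    rng_seed: int | None = None
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        for name in ("population_size", "n_generations", "selection_size",
                     "elite_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("blend_rate", "crossover_rate", "mutation_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_magnitude <= 0:
            raise ValueError("mutation_magnitude must be positive")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be below population_size")


@dataclass
class FitResult:
    """Outcome of one GA run."""

    weights: np.ndarray
    objective_value: float
    ordinal_fit_rmse: float
    generations_run: int
    converged: bool
    history: np.ndarray = field(repr=False, default=None)  # best per generation


# --------------------------------------------------------------------------- #
# Objective


def modeled_trajectory(
    W_hat, panel: ObservedPanel, n_steps: int | None = None
) -> np.ndarray:
    """Plain-DeGroot trajectory implied by ``W_hat`` and the panel's t = 0.

    Initial opinions are the forward-transformed observed scores at t = 0;
    the model then steps through every integer time index up to ``n_steps``
    (default: the last observed step), including unobserved intermediate
    steps so indirect influence can propagate.
    """
    W_hat = np.asarray(W_hat, dtype=float)
    if W_hat.shape != (panel.n_agents, panel.n_agents):
        raise ValueError(
            f"weight matrix {W_hat.shape} does not match panel of "
            f"{panel.n_agents} agents"
        )
    if n_steps is None:
        n_steps = panel.observed_steps[-1]
    x = panel.continuous_opinions[:, 0]
    out = np.empty((panel.n_agents, n_steps + 1))
    out[:, 0] = x
    for t in range(n_steps):
        x = W_hat @ x
        out[:, t + 1] = x
    return out


def _binned_penalty(x_model, obs_cont, obs_levels, scale, t):
    """Penalty contribution of one observed step: sum_i B_i * |gap_i|.

    ``x_model`` may be (M,) or batched (P, M); the sum runs over the last
    axis.  ``t`` identifies the observed step for diagnostics.
    """
    levels = scale._back_unchecked(np.clip(x_model, 0.0, 1.0))
    B = np.abs(levels - obs_levels)
    return (B * np.abs(x_model - obs_cont)).sum(axis=-1)


def _population_objective(pop: np.ndarray, panel: ObservedPanel) -> np.ndarray:
    """Objective of every chromosome in ``pop`` (shape (P, M, M))."""
    cont = panel.continuous_opinions
    observed = {t: k for k, t in enumerate(panel.observed_steps)}
    t_max = panel.observed_steps[-1]
    X = np.broadcast_to(cont[:, 0], pop.shape[:1] + (panel.n_agents,)).copy()
    total = np.zeros(pop.shape[0])
    for t in range(1, t_max + 1):
        X = np.einsum("pij,pj->pi", pop, X)
        k = observed.get(t)
        if k is not None:
            total += _binned_penalty(
                X, cont[:, k], panel.ordinal_opinions[:, k], panel.scale, t
            )
    return total


def objective_by_agent(W_hat, panel: ObservedPanel) -> np.ndarray:
    """Per-agent objective contributions (the row-level decomposition)."""
    traj = modeled_trajectory(W_hat, panel)
    cont = panel.continuous_opinions
    out = np.zeros(panel.n_agents)
    for k, t in enumerate(panel.observed_steps):
        if t == 0:
            continue
        x = traj[:, t]
        levels = panel.scale._back_unchecked(np.clip(x, 0.0, 1.0))
        B = np.abs(levels - panel.ordinal_opinions[:, k])
        out += B * np.abs(x - cont[:, k])
    return out


def objective(W_hat, panel: ObservedPanel) -> float:
    """Bin-penalised objective of a candidate weight matrix.

    Sum over agents and observed non-initial steps of
    ``bin_deviation * |modeled - observed|`` on the continuous scale.  The
    t = 0 term is identically zero (the model starts at the observed values)
    and is not evaluated.
    """
    return float(objective_by_agent(W_hat, panel).sum())


def row_objective(W_hat, panel: ObservedPanel, agent: int) -> float:
    """Objective restricted to one agent's row."""
    if not (0 <= agent < panel.n_agents):
        raise IndexError(f"agent index {agent} out of range")
    return float(objective_by_agent(W_hat, panel)[agent])


def _ordinal_fit_rmse(W_hat, panel: ObservedPanel) -> float:
    """RMSE of bin deviations over observed non-initial steps, scaled by n."""
    traj = modeled_trajectory(W_hat, panel)
    n = panel.scale.n_points
    total = 0.0
    count = 0
    for k, t in enumerate(panel.observed_steps):
        if t == 0:
            continue
        levels = panel.scale._back_unchecked(np.clip(traj[:, t], 0.0, 1.0))
        B = np.abs(levels - panel.ordinal_opinions[:, k])
        total += float((B.astype(float) ** 2).sum())
        count += panel.n_agents
    return float(np.sqrt(total / (count * n**2)))


# --------------------------------------------------------------------------- #
# Genetic algorithm


def random_chromosome(adjacency, rng: np.random.Generator) -> np.ndarray:
    """Uniform random feasible weight matrix for the given adjacency."""
    A = validate_adjacency(adjacency)
    U = rng.random(A.shape) * A
    return U / U.sum(axis=1, keepdims=True)


def _normalize_rows(pop: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Renormalise rows to sum one; a zero row falls back to unit self-weight."""
    sums = pop.sum(axis=-1, keepdims=True)
    dead = (sums == 0.0)[..., 0]
    if np.any(dead):
        eye = np.broadcast_to(np.eye(pop.shape[-1]), pop.shape)
        pop = np.where(dead[..., None], eye, pop)
        sums = pop.sum(axis=-1, keepdims=True)
    return pop / sums


def ga_fit(
    panel: ObservedPanel,
    config: GAConfig | None = None,
    on_generation=None,
) -> FitResult:
    """Evolve a population of weight matrices against the panel.

    Each generation keeps the ``elite_count`` best chromosomes unchanged and
    refills the population with offspring: two parents per offspring chosen
    by tournament, then crossover (gene exchange), blending (per-gene convex
    combination) and mutation applied at their configured rates.  The best
    objective is non-increasing across generations; the search stops early
    once it reaches ``config.tolerance``.

    ``on_generation(generation, population, objectives)`` is an optional
    diagnostics hook invoked after each generation is formed.
    """
    config = GAConfig() if config is None else config
    rng = np.random.default_rng(config.rng_seed)
    A = panel.adjacency
    mask = A.astype(bool)
    M = panel.n_agents
    P = config.population_size
    n_children = P - config.elite_count

    U = rng.random((P, M, M)) * A
    pop = _normalize_rows(U, mask)
    obj = _population_objective(pop, panel)

    history = []
    generations = 0
    converged = bool(obj.min() <= config.tolerance)
    for gen in range(config.n_generations):
        if converged:
            break
        order = np.argsort(obj, kind="stable")
        elite = pop[order[: config.elite_count]]
        elite_obj = obj[order[: config.elite_count]]

        # tournament selection of two parents per offspring
        cand = rng.integers(0, P, size=(n_children, 2, config.selection_size))
        winners = cand[
            np.arange(n_children)[:, None],
            np.arange(2)[None, :],
            np.argmin(obj[cand], axis=2),
        ]
        p1 = pop[winners[:, 0]]
        p2 = pop[winners[:, 1]]

        child = p1.copy()
        # crossover: exchange whole genes (rows) with the second parent
        do_cross = rng.random(n_children) < config.crossover_rate
        swap = (rng.random((n_children, M)) < 0.5) & do_cross[:, None]
        child[swap] = p2[swap]
        # blending: per-gene convex combination with a random coefficient
        do_blend = rng.random(n_children) < config.blend_rate
        u = rng.random((n_children, M, 1))
        child = np.where(
            do_blend[:, None, None], u * child + (1.0 - u) * p2, child
        )
        # mutation: perturb permitted entries of selected genes, renormalise
        do_mut = rng.random((n_children, M)) < config.mutation_rate
        noise = rng.normal(0.0, config.mutation_magnitude, (n_children, M, M)) * A
        mutated = np.clip(child + noise, 0.0, None)
        child = np.where(do_mut[:, :, None], mutated, child)
        child = _normalize_rows(child, mask)

        child_obj = _population_objective(child, panel)
        pop = np.concatenate([elite, child])
        obj = np.concatenate([elite_obj, child_obj])
        generations = gen + 1
        history.append(obj.min())
        if on_generation is not None:
            on_generation(generations, pop, obj)
        converged = bool(obj.min() <= config.tolerance)

    best = int(np.argmin(obj))
    W_best = pop[best]
    return FitResult(
        weights=W_best,
        objective_value=float(obj[best]),
        ordinal_fit_rmse=_ordinal_fit_rmse(W_best, panel),
        generations_run=generations,
        converged=converged,
        history=np.asarray(history),
    )


def average_fits(weight_matrices) -> np.ndarray:
    """Entrywise mean of fitted weight matrices from multiple runs.

    Averaging preserves both the sum-to-one constraint and shared structural
    zeros, so the mean is itself an admissible weight matrix.
    """
    mats = [np.asarray(w, dtype=float) for w in weight_matrices]
    if not mats:
        raise ValueError("need at least one weight matrix to average")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all weight matrices must share one shape")
    return np.mean(mats, axis=0)
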