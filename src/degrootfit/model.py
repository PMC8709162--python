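"""Model/Results interface for fitting DeGroot models to opinion panels.

``DeGrootModel`` holds the data — an ordinal opinion panel, the adjacency
matrix the analyst is willing to assume, and the scale — and ``fit()`` runs
the genetic algorithm, returning a ``DeGrootResults`` with the estimated
influence-weight matrix, fit diagnostics, and prediction helpers.

Because the objective surface has many perfect-fit local minima (several
weight matrices can reproduce the same ordinal panel, especially on coarse
scales with few time steps), ``fit(n_runs=...)`` supports multiple
independently seeded runs; averaging their weight matrices preserves the
sum-to-one constraint and is exposed via ``average=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import (
    FitResult,
    GAConfig,
    average_fits,
    ga_fit,
    modeled_trajectory,
    objective,
    objective_by_agent,
)
from .metrics import LeaderInfluence, leader_influence_summary
from .panel import ObservedPanel
from .scale import OrdinalScale

__all__ = ["DeGrootModel", "DeGrootResults"]


class DeGrootModel:
    """DeGroot opinion-diffusion model on an observed ordinal panel.

    Parameters
    ----------
    ordinal_opinions : (M, K) integer array
        Scores in 1..n_points, one column per observed time step.
    adjacency : (M, M) symmetric binary matrix with unit diagonal
        Potential-influence structure; zeros become structural zeros of the
        estimated weight matrix.
    n_points : int
        Number of points of the ordinal scale.
    observed_steps : increasing time indices starting at 0
        Defaults to 0..K-1.  Gaps are allowed; the model simulates through
        unobserved steps.
    agent_ids : optional row labels.
    """

    def __init__(
        self,
        ordinal_opinions,
        adjacency,
        n_points: int,
        observed_steps=None,
        agent_ids=None,
    ):
        scores = np.asarray(ordinal_opinions)
        if observed_steps is None:
            observed_steps = tuple(range(scores.shape[1]))
        self.panel = ObservedPanel(
            ordinal_opinions=scores,
            observed_steps=tuple(observed_steps),
            scale=OrdinalScale(int(n_points)),
            adjacency=adjacency,
            agent_ids=agent_ids,
        )

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, adjacency, n_points: int):
        """Build from a DataFrame with columns named t0, t1/t3, ... ."""
        p = ObservedPanel.from_frame(panel, adjacency, n_points)
        return cls(
            p.ordinal_opinions,
            p.adjacency,
            p.scale.n_points,
            observed_steps=p.observed_steps,
            agent_ids=p.agent_ids,
        )

    @property
    def n_agents(self) -> int:
        return self.panel.n_agents

    def fit(
        self,
        config: GAConfig | None = None,
        n_runs: int = 1,
        average: bool = False,
        seed: int | None = None,
    ) -> "DeGrootResults":
        """Fit by genetic algorithm, optionally over several seeded runs.

        ``seed`` spawns one independent stream per run; with ``average``
        the reported weights are the entrywise mean across runs, otherwise
        those of the best-objective run.
        """
        if n_runs < 1:
            raise ValueError("n_runs must be positive")
        config = GAConfig() if config is None else config
        seeds = np.random.SeedSequence(seed).spawn(n_runs)
        runs = []
        for ss in seeds:
            run_seed = int(ss.generate_state(1)[0] % (2**31))
            from dataclasses import replace

            runs.append(ga_fit(self.panel, replace(config, rng_seed=run_seed)))
        return DeGrootResults(self, runs, averaged=average)

    def objective(self, weights) -> float:
        """Bin-penalised objective of an arbitrary candidate weight matrix."""
        return objective(weights, self.panel)


class DeGrootResults:
    """Estimates and diagnostics from one or more GA runs."""

    def __init__(self, model: DeGrootModel, runs: list[FitResult], averaged=False):
        if not runs:
            raise ValueError("need at least one run")
        self.model = model
        self.runs = runs
        self.averaged = bool(averaged)
        self._best = min(range(len(runs)), key=lambda i: runs[i].objective_value)
        if self.averaged and len(runs) > 1:
            self._weights = average_fits([r.weights for r in runs])
        else:
            self._weights = runs[self._best].weights

    # ------------------------------------------------------------------ #
    @property
    def weights(self) -> pd.DataFrame:
        """Estimated weight matrix with agent ids on both axes."""
        ids = list(self.model.panel.agent_ids)
        return pd.DataFrame(self._weights, index=ids, columns=ids)

    @property
    def params(self) -> np.ndarray:
        """Estimated weight matrix as an array (alias of ``weights``)."""
        return self._weights

    @property
    def best_run(self) -> FitResult:
        return self.runs[self._best]

    @property
    def objective_value(self) -> float:
        """Objective of the reported weight matrix."""
        return self.model.objective(self._weights)

    @property
    def ordinal_fit_rmse(self) -> float:
        return self.best_run.ordinal_fit_rmse

    @property
    def converged(self) -> bool:
        return self.best_run.converged

    def objective_by_agent(self) -> pd.Series:
        """Per-agent (row-level) objective decomposition."""
        return pd.Series(
            objective_by_agent(self._weights, self.model.panel),
            index=list(self.model.panel.agent_ids),
            name="objective",
        )

    def predict(self, n_steps: int = 20) -> pd.DataFrame:
        """Continuous trajectory implied by the fit, columns t0..t<n_steps>."""
        traj = modeled_trajectory(self._weights, self.model.panel, n_steps)
        return pd.DataFrame(
            traj,
            index=list(self.model.panel.agent_ids),
            columns=[f"t{t}" for t in range(n_steps + 1)],
        )

    def predict_ordinal(self, n_steps: int = 20) -> pd.DataFrame:
        """Predicted trajectory back-transformed to the ordinal scale."""
        cont = self.predict(n_steps)
        scale = self.model.panel.scale
        return cont.apply(lambda col: scale.back(np.clip(col.to_numpy(), 0, 1)))

    def leader_influence(
        self, leader_flags, exclusion_threshold: float | None = None
    ) -> LeaderInfluence:
        """Mean estimated weight placed on leaders vs non-leaders."""
        return leader_influence_summary(
            self._weights,
            leader_flags,
            adjacency=self.model.panel.adjacency,
            exclusion_threshold=exclusion_threshold,
        )

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        panel = self.model.panel
        lines = [
            "DeGroot opinion-diffusion model — genetic-algorithm fit",
            "=" * 56,
            f"agents:             {panel.n_agents}",
            f"observed steps:     {list(panel.observed_steps)}",
            f"ordinal scale:      {panel.scale.n_points} points",
            f"runs:               {len(self.runs)}"
            + ("  (weights averaged)" if self.averaged else ""),
            f"objective:          {self.objective_value:.6g}",
            f"ordinal fit RMSE:   {self.ordinal_fit_rmse:.6g}",
            f"generations (best): {self.best_run.generations_run}",
            f"converged:          {self.converged}",
            "",
            "Estimated weight matrix:",
            self.weights.round(3).to_string(),
        ]
        if len(self.runs) > 1:
            per_run = ", ".join(f"{r.objective_value:.4g}" for r in self.runs)
            lines.insert(9, f"per-run objectives: {per_run}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DeGrootResults agents={self.model.n_agents} "
            f"objective={self.objective_value:.4g} runs={len(self.runs)}>"
        )
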