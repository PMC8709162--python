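"""Performance metrics for the simulation study.

Four root-mean-square errors summarise a run.  Recovery compares estimated
and true weights over the entries the fitter was allowed to estimate (the
parameter count P).  Modeling and prediction compare the fitted model's
continuous trajectory with the latent trajectory of the sampled agents —
modeling on the fitted steps t = 1..T-1, prediction on the held-out steps
t = T..20.  Ordinal fit is the analyst-facing analogue of modeling: bin
deviations on the fitted steps, scaled by the number of scale points.

The true weight matrix is reduced to the sampled agents without
renormalisation, so its rows may sum to less than one — weight placed on
agents missing from the sample is simply unaccounted for.  For runs fitted
with the build matrix, recovery is evaluated against the correct matrix so
that incorrectly assumed structural zeros are penalised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .scale import OrdinalScale

__all__ = [
    "EvaluationContext",
    "LeaderInfluence",
    "recovery_rmse",
    "row_recovery_rmse",
    "modeling_rmse",
    "prediction_rmse",
    "ordinal_fit_rmse",
    "leader_influence_summary",
]


@dataclass
class EvaluationContext:
    """Everything needed to score one simulation run.

    true_weights_reduced : (M, M) true weights restricted to sampled agents
        (rows may sum below one).
    estimated_weights : (M, M) fitted weight matrix.
    eval_adjacency : adjacency used to count parameters P — the variety given
        to the fitter, except build runs, which are scored against correct.
    latent_trajectory : (M, 21) true continuous opinions of sampled agents.
    modeled_trajectory : (M, 21) fitted model's continuous opinions.
    T : number of time steps the fitter saw (t = 0..T-1).
    scale : the ordinal scale of the panel.
    """

    true_weights_reduced: np.ndarray
    estimated_weights: np.ndarray
    eval_adjacency: np.ndarray
    latent_trajectory: np.ndarray
    modeled_trajectory: np.ndarray
    T: int
    scale: OrdinalScale


class LeaderInfluence(NamedTuple):
    leader_mean: Optional[float]
    non_leader_mean: Optional[float]
    difference: Optional[float]


def row_recovery_rmse(true_row, est_row, permitted) -> float:
    """Recovery RMSE over one agent's permitted (non-structural-zero) entries."""
    true_row = np.asarray(true_row, dtype=float)
    est_row = np.asarray(est_row, dtype=float)
    keep = np.asarray(permitted, dtype=bool)
    if true_row.shape != est_row.shape or keep.shape != true_row.shape:
        raise ValueError("row shapes do not agree")
    P = int(keep.sum())
    if P == 0:
        raise ValueError("no permitted entries in the row")
    diff = true_row[keep] - est_row[keep]
    return float(np.sqrt((diff**2).sum() / P))


def recovery_rmse(ctx: EvaluationContext) -> float:
    """RMSE of estimated vs true weights over the P permitted entries."""
    keep = np.asarray(ctx.eval_adjacency, dtype=bool)
    diff = np.asarray(ctx.true_weights_reduced) - np.asarray(ctx.estimated_weights)
    P = int(keep.sum())
    return float(np.sqrt((diff[keep] ** 2).sum() / P))


def modeling_rmse(ctx: EvaluationContext) -> float:
    """RMSE of modeled vs latent opinions on fitted steps t = 1..T-1."""
    if ctx.T < 2:
        raise ValueError("modeling RMSE needs at least two fitted steps")
    M = ctx.latent_trajectory.shape[0]
    diff = ctx.modeled_trajectory[:, 1 : ctx.T] - ctx.latent_trajectory[:, 1 : ctx.T]
    return float(np.sqrt((diff**2).sum() / (M * (ctx.T - 1))))


def prediction_rmse(ctx: EvaluationContext) -> float:
    """RMSE of modeled vs latent opinions on held-out steps t = T..20."""
    horizon = ctx.latent_trajectory.shape[1] - 1  # typically 20
    if ctx.T > horizon:
        raise ValueError("no held-out steps to predict")
    M = ctx.latent_trajectory.shape[0]
    diff = (
        ctx.modeled_trajectory[:, ctx.T : horizon + 1]
        - ctx.latent_trajectory[:, ctx.T : horizon + 1]
    )
    return float(np.sqrt((diff**2).sum() / (M * (horizon + 1 - ctx.T))))


def ordinal_fit_rmse(ctx: EvaluationContext) -> float:
    """RMSE of bin deviations on fitted steps, scaled by the scale size."""
    if ctx.T < 2:
        raise ValueError("ordinal fit needs at least two fitted steps")
    M = ctx.latent_trajectory.shape[0]
    n = ctx.scale.n_points
    model_levels = ctx.scale._back_unchecked(
        np.clip(ctx.modeled_trajectory[:, 1 : ctx.T], 0.0, 1.0)
    )
    obs_levels = ctx.scale._back_unchecked(
        np.clip(ctx.latent_trajectory[:, 1 : ctx.T], 0.0, 1.0)
    )
    B = np.abs(model_levels - obs_levels).astype(float)
    return float(np.sqrt((B**2).sum() / (M * (ctx.T - 1) * n**2)))


def leader_influence_summary(
    weights,
    leader_flags,
    adjacency=None,
    exclusion_threshold: float | None = None,
) -> LeaderInfluence:
    """Mean weight placed on leaders vs non-leaders.

    Self-weights are excluded, as are rows of agents with no permitted link
    to any leader.  ``adjacency`` restricts which entries count as links
    (complete if omitted).  ``exclusion_threshold`` optionally drops
    estimated weights at or below it — useful when correctly estimated
    structural zeros would dilute the means, at the cost of inflating
    influence when a zero reflects a genuine failure to influence.

    Returns means and their difference (leader minus non-leader); a mean is
    None when its entry set is empty (e.g. every agent is a leader).
    """
    W = np.asarray(weights, dtype=float)
    leaders = np.asarray(leader_flags, dtype=bool)
    M = W.shape[0]
    if leaders.shape != (M,):
        raise ValueError("one leader flag per agent required")
    if not leaders.any():
        raise ValueError("at least one leader required")
    A = np.ones((M, M)) if adjacency is None else np.asarray(adjacency, dtype=float)
    offdiag = ~np.eye(M, dtype=bool)
    linked = (A > 0) & offdiag
    has_leader_link = (linked & leaders[None, :]).any(axis=1)

    def _mean(target_cols: np.ndarray) -> Optional[float]:
        sel = linked & target_cols[None, :] & has_leader_link[:, None]
        vals = W[sel]
        if exclusion_threshold is not None:
            vals = vals[vals > exclusion_threshold]
        return float(vals.mean()) if vals.size else None

    leader_mean = _mean(leaders)
    non_leader_mean = _mean(~leaders)
    difference = (
        leader_mean - non_leader_mean
        if leader_mean is not None and non_leader_mean is not None
        else None
    )
    return LeaderInfluence(leader_mean, non_leader_mean, difference)
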