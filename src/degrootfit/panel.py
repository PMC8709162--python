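"""Observed ordinal opinion panels: the data object the fitter consumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import validate_adjacency
from .scale import OrdinalScale

__all__ = ["ObservedPanel"]


@dataclass(frozen=True)
class ObservedPanel:
    """Ordinal opinions of M agents at K observed time steps, plus structure.

    Parameters
    ----------
    ordinal_opinions : (M, K) integer array
        Scores in 1..n, one column per observed step.
    observed_steps : strictly increasing integer time indices
        Must start at 0: the initial opinions anchor the simulation.  Steps
        may be non-consecutive — observations three months apart can be coded
        as t = 0 and t = 3 with t = 1, 2 unobserved, letting the model step
        through the gap so indirect influence can accumulate.
    scale : OrdinalScale
    adjacency : (M, M) adjacency variety given to the fitter
    agent_ids : optional labels, defaults to 0..M-1
    """

    ordinal_opinions: np.ndarray
    observed_steps: tuple[int, ...]
    scale: OrdinalScale
    adjacency: np.ndarray
    agent_ids: tuple = field(default=None)

    def __post_init__(self) -> None:
        scores = np.asarray(self.ordinal_opinions)
        if scores.ndim != 2:
            raise ValueError("ordinal opinions must be a 2-D agents x steps table")
        if not np.issubdtype(scores.dtype, np.integer):
            if np.any(np.isnan(scores.astype(float))):
                raise ValueError(
                    "panel contains missing values; the fitter requires "
                    "complete panels (impute before fitting)"
                )
            if not np.all(np.equal(np.mod(scores, 1), 0)):
                raise ValueError("ordinal opinions must be integers")
            scores = scores.astype(np.int64)
        if np.any(scores < 1) or np.any(scores > self.scale.n_points):
            raise ValueError(
                f"scores must lie in 1..{self.scale.n_points}"
            )
        steps = tuple(int(t) for t in self.observed_steps)
        if len(steps) != scores.shape[1]:
            raise ValueError("one observed step per panel column required")
        if steps[0] != 0:
            raise ValueError("the first observed step must be t = 0")
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("observed steps must be strictly increasing")
        A = validate_adjacency(self.adjacency)
        if A.shape[0] != scores.shape[0]:
            raise ValueError("adjacency size does not match the panel")
        ids = self.agent_ids
        ids = tuple(range(scores.shape[0])) if ids is None else tuple(ids)
        if len(ids) != scores.shape[0]:
            raise ValueError("one agent id per panel row required")
        object.__setattr__(self, "ordinal_opinions", scores)
        object.__setattr__(self, "observed_steps", steps)
        object.__setattr__(self, "adjacency", A)
        object.__setattr__(self, "agent_ids", ids)

    @property
    def n_agents(self) -> int:
        return self.ordinal_opinions.shape[0]

    @property
    def n_observed(self) -> int:
        return len(self.observed_steps)

    @property
    def continuous_opinions(self) -> np.ndarray:
        """Forward-transformed (bin-midpoint) opinions, shape (M, K)."""
        return self.scale.forward(self.ordinal_opinions)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with agent ids as index and t<k> column labels."""
        return pd.DataFrame(
            self.ordinal_opinions,
            index=pd.Index(self.agent_ids, name="agent"),
            columns=[f"t{t}" for t in self.observed_steps],
        )

    @classmethod
    def from_frame(cls, panel, adjacency, n_points: int) -> "ObservedPanel":
        """Build a panel from DataFrames (columns named t0, t3, ...)."""
        panel = pd.DataFrame(panel)
        steps = tuple(int(str(c).lstrip("t")) for c in panel.columns)
        adj = pd.DataFrame(adjacency)
        return cls(
            ordinal_opinions=panel.to_numpy(),
            observed_steps=steps,
            scale=OrdinalScale(n_points),
            adjacency=adj.to_numpy(),
            agent_ids=tuple(panel.index),
        )
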