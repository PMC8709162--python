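"""Delimited-text serialisation of matrices, trajectories, panels and samples.

Everything is plain CSV via pandas: square matrices with agent ids on both
axes, trajectories with a ``t<k>`` header per time step, panels likewise
(possibly with gaps, e.g. ``t0,t3``), and snowball samples as a two-column
``agent_id,wave`` table plus a recruiter/recruit edge list.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import GAConfig
from .panel import ObservedPanel
from .sampling import SampledNetwork

__all__ = [
    "write_matrix", "read_matrix",
    "write_trajectory", "read_trajectory",
    "write_panel", "read_panel",
    "write_sample", "read_sample",
    "read_ga_config", "write_ga_config",
]


def write_matrix(path, matrix, agent_ids=None) -> None:
    """Write a square matrix with agent ids as index and header."""
    matrix = np.asarray(matrix)
    ids = list(range(matrix.shape[0])) if agent_ids is None else list(agent_ids)
    df = pd.DataFrame(matrix, index=ids, columns=ids)
    df.to_csv(path, index_label="agent")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_trajectory(path, trajectory, agent_ids=None, t_start: int = 0) -> None:
    """Write an (N, K) trajectory with columns t<t_start>..t<t_start+K-1>."""
    trajectory = np.asarray(trajectory)
    ids = list(range(trajectory.shape[0])) if agent_ids is None else list(agent_ids)
    cols = [f"t{t_start + k}" for k in range(trajectory.shape[1])]
    pd.DataFrame(trajectory, index=ids, columns=cols).to_csv(
        path, index_label="agent"
    )


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_panel(path, panel: ObservedPanel) -> None:
    panel.to_frame().to_csv(path)


def read_panel(panel_path, adjacency_path, n_points: int) -> ObservedPanel:
    """Read a panel (columns t0,t3,...) and its adjacency matrix."""
    panel = pd.read_csv(panel_path, index_col=0)
    if panel.isna().any().any():
        raise ValueError(
            f"{panel_path}: panel contains missing values; the fitter "
            "requires complete panels (impute before fitting)"
        )
    adjacency = read_matrix(adjacency_path)
    return ObservedPanel.from_frame(panel, adjacency, n_points)


def write_sample(agents_path, edges_path, sample: SampledNetwork) -> None:
    """Write sample membership (agent_id, wave) and the recruitment tree."""
    pd.DataFrame(
        {"agent_id": list(sample.sampled_ids),
         "wave": [sample.wave_of[i] for i in sample.sampled_ids]}
    ).to_csv(agents_path, index=False)
    pd.DataFrame(
        sample.recruitment_edges, columns=["recruiter", "recruit"]
    ).to_csv(edges_path, index=False)


def read_sample(agents_path, edges_path) -> SampledNetwork:
    agents = pd.read_csv(agents_path)
    edges = pd.read_csv(edges_path)
    wave_of = dict(zip(agents["agent_id"].astype(int), agents["wave"].astype(int)))
    seed = int(agents.loc[agents["wave"] == 0, "agent_id"].iloc[0])
    return SampledNetwork(
        sampled_ids=tuple(agents["agent_id"].astype(int)),
        wave_of=wave_of,
        recruitment_edges=tuple(
            (int(a), int(b)) for a, b in edges.itertuples(index=False)
        ),
        seed_id=seed,
    )


def read_ga_config(path) -> GAConfig:
    """Load a GAConfig from a flat YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    valid = set(GAConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown GA config keys {sorted(unknown)}")
    return GAConfig(**raw)


def write_ga_config(path, config: GAConfig) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
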