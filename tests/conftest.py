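import numpy as np
import pytest

from degrootfit import (
    DynamicsSpec,
    ObservedPanel,
    OrdinalScale,
    generate_weight_matrix,
    simulate_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(N, rng, p=0.5):
    """Random symmetric 0/1 matrix with unit diagonal (not necessarily connected)."""
    upper = np.triu(rng.random((N, N)) < p, k=1)
    A = (upper | upper.T).astype(float)
    np.fill_diagonal(A, 1.0)
    return A


def random_weights(N, rng, p=0.5):
    """Random feasible weight matrix on a random adjacency."""
    A = random_adjacency(N, rng, p)
    U = rng.random((N, N)) * A
    return U / U.sum(axis=1, keepdims=True), A


def make_noiseless_panel(n_agents, n_points, T, seed, spec=DynamicsSpec()):
    """Panel discretised from a trajectory simulated on a known weight matrix.

    Returns (panel, true_weights, latent_trajectory).  The adjacency is
    complete, so the generating weights are admissible for the fitter.
    """
    rng = np.random.default_rng(seed)
    A = np.ones((n_agents, n_agents))
    W = generate_weight_matrix(A, rng)
    x0 = rng.random(n_agents)
    traj = simulate_trajectory(W, x0, T - 1, spec)
    scale = OrdinalScale(n_points)
    panel = ObservedPanel(
        ordinal_opinions=scale.back(traj),
        observed_steps=tuple(range(T)),
        scale=scale,
        adjacency=A,
    )
    return panel, W, traj
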