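"""Ground-truth generation and two-wave snowball sampling.

The simulation harness generates Erdős–Rényi networks (rejecting disconnected
draws), row-stochastic weight matrices with Beta-distributed self-weights,
and uniform initial opinions; it then emulates the recruitment process of a
field study: a maximum-degree seed, two waves of Bernoulli(p) recruitment,
and one of four adjacency-matrix varieties describing what the analyst is
willing to assume about links among the sampled agents:

``correct``   true links among sampled agents (a baseline, rarely available),
``build``     only links implied by the recruitment chain,
``remove``    all links except those the seed is known not to have,
``complete``  all links.

Entrywise, build <= correct <= remove <= complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dynamics import DynamicsSpec, DEGROOT, simulate_trajectory, validate_adjacency

__all__ = [
    "GroundTruth",
    "SampledNetwork",
    "GenerationError",
    "SampleRejectedError",
    "ADJACENCY_KINDS",
    "generate_er_network",
    "generate_weight_matrix",
    "generate_initial_opinions",
    "generate_ground_truth",
    "snowball_sample",
    "sample_with_rejection",
    "build_adjacency_variety",
]

ADJACENCY_KINDS = ("correct", "build", "remove", "complete")


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its retry budget."""


class SampleRejectedError(RuntimeError):
    """Raised when a snowball sample recruits fewer than four agents."""


@dataclass(frozen=True)
class SampledNetwork:
    """Outcome of a two-wave snowball sample on a known network.

    ``sampled_ids`` lists original agent indices in sampling order (seed
    first, then wave 1 in trial order, then wave 2).  ``recruitment_edges``
    form a tree rooted at the seed: one (recruiter, recruit) pair per
    non-seed agent.
    """

    sampled_ids: tuple[int, ...]
    wave_of: dict[int, int]
    recruitment_edges: tuple[tuple[int, int], ...]
    seed_id: int

    @property
    def size(self) -> int:
        return len(self.sampled_ids)

    def waves(self) -> np.ndarray:
        """Wave labels aligned with ``sampled_ids``."""
        return np.array([self.wave_of[i] for i in self.sampled_ids])


@dataclass
class GroundTruth:
    """A fully known network, weight matrix and simulated trajectory."""

    adjacency: np.ndarray
    weights: np.ndarray
    initial_opinions: np.ndarray
    trajectory: np.ndarray  # (N, n_steps + 1), column t is X(t)
    spec: DynamicsSpec = field(default=DEGROOT)

    @property
    def size(self) -> int:
        return self.adjacency.shape[0]


def generate_er_network(
    N: int, d: float, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Draw a connected Erdős–Rényi adjacency matrix with self-links.

    Each off-diagonal pair is linked independently with probability
    d / (N - 1), giving expected degree d.  Draws are rejected until the
    graph (ignoring self-links) is connected, which also guarantees minimum
    degree 1.
    """
    if N < 2:
        raise ValueError(f"network size must be at least 2, got {N}")
    if not (1 <= d <= N - 1):
        raise ValueError(f"target degree must lie in 1..{N - 1}, got {d}")
    p_edge = d / (N - 1)
    for _ in range(max_tries):
        upper = rng.random((N, N)) < p_edge
        A = np.triu(upper, k=1)
        A = (A | A.T).astype(float)
        np.fill_diagonal(A, 1.0)
        G = nx.from_numpy_array(A - np.eye(N))
        if nx.is_connected(G):
            return A
    raise GenerationError(
        f"no connected network in {max_tries} tries (N={N}, d={d})"
    )


def generate_weight_matrix(
    A,
    rng: np.random.Generator,
    target_self_weight: float = 0.5,
    kappa: float = 4.0,
    neighbor_split: str = "uniform",
) -> np.ndarray:
    """Draw a row-stochastic weight matrix respecting the adjacency.

    Self-weights come from a Beta distribution with mean
    ``target_self_weight`` and concentration alpha + beta = ``kappa``
    (Beta(2, 2) at the defaults).  The remaining mass of each row is split
    across the agent's neighbours, either evenly (``uniform``) or by a
    symmetric Dirichlet draw (``dirichlet``).  An isolated agent (self-link
    only) gets self-weight 1.
    """
    A = validate_adjacency(A)
    if not (0.0 < target_self_weight < 1.0):
        raise ValueError("target self-weight must lie in (0, 1)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if neighbor_split not in ("uniform", "dirichlet"):
        raise ValueError(f"unknown neighbor_split {neighbor_split!r}")
    N = A.shape[0]
    alpha = target_self_weight * kappa
    beta = (1.0 - target_self_weight) * kappa
    W = np.zeros((N, N))
    for i in range(N):
        neighbors = np.nonzero(A[i])[0]
        neighbors = neighbors[neighbors != i]
        if neighbors.size == 0:
            W[i, i] = 1.0
            continue
        wii = rng.beta(alpha, beta)
        W[i, i] = wii
        rest = 1.0 - wii
        if neighbor_split == "uniform":
            W[i, neighbors] = rest / neighbors.size
        else:
            W[i, neighbors] = rest * rng.dirichlet(np.ones(neighbors.size))
    return W


def generate_initial_opinions(N: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. Uniform(0, 1) initial opinions."""
    if N < 1:
        raise ValueError(f"need at least one agent, got N={N}")
    return rng.random(N)


def generate_ground_truth(
    N: int,
    d: float,
    rng: np.random.Generator,
    target_self_weight: float = 0.5,
    kappa: float = 4.0,
    spec: DynamicsSpec = DEGROOT,
    n_steps: int = 20,
    neighbor_split: str = "uniform",
    max_tries: int = 1000,
) -> GroundTruth:
    """Generate network, weights, initial opinions and a simulated trajectory."""
    A = generate_er_network(N, d, rng, max_tries=max_tries)
    W = generate_weight_matrix(
        A, rng, target_self_weight=target_self_weight, kappa=kappa,
        neighbor_split=neighbor_split,
    )
    x0 = generate_initial_opinions(N, rng)
    traj = simulate_trajectory(W, x0, n_steps, spec)
    return GroundTruth(A, W, x0, traj, spec)


def snowball_sample(A, p: float, rng: np.random.Generator) -> SampledNetwork:
    """Simulate a two-wave snowball sample with recruitment probability p.

    The seed is a maximum-degree agent (ties broken uniformly at random).
    Every neighbour of the seed undergoes one Bernoulli(p) trial (wave 1);
    every not-yet-tried neighbour of each wave-1 recruit undergoes one trial
    (wave 2).  Each agent is tried at most once — an agent who declines is
    excluded for good — and recruitment stops after two waves.  Trials run in
    ascending agent index within each recruiter, recruiters in sampling
    order, so the draw sequence is reproducible.

    Raises
    ------
    SampleRejectedError
        If fewer than four agents (seed included) are sampled.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"recruitment probability must lie in (0, 1], got {p}")
    A = validate_adjacency(A)
    N = A.shape[0]
    degrees = A.sum(axis=1) - 1.0
    top = np.nonzero(degrees == degrees.max())[0]
    seed = int(top[rng.integers(top.size)]) if top.size > 1 else int(top[0])

    tried = {seed}
    wave_of = {seed: 0}
    sampled = [seed]
    edges: list[tuple[int, int]] = []

    def neighbors(i: int) -> np.ndarray:
        nb = np.nonzero(A[i])[0]
        return nb[nb != i]

    wave1: list[int] = []
    for j in neighbors(seed):
        j = int(j)
        tried.add(j)
        if rng.random() < p:
            wave1.append(j)
            wave_of[j] = 1
            sampled.append(j)
            edges.append((seed, j))
    for r in wave1:
        for j in neighbors(r):
            j = int(j)
            if j in tried:
                continue
            tried.add(j)
            if rng.random() < p:
                wave_of[j] = 2
                sampled.append(j)
                edges.append((r, j))
    if len(sampled) < 4:
        raise SampleRejectedError(
            f"snowball sample recruited only {len(sampled)} agents"
        )
    return SampledNetwork(tuple(sampled), wave_of, tuple(edges), seed)


def sample_with_rejection(
    N: int,
    d: float,
    p: float,
    rng: np.random.Generator,
    target_self_weight: float = 0.5,
    kappa: float = 4.0,
    spec: DynamicsSpec = DEGROOT,
    n_steps: int = 20,
    neighbor_split: str = "uniform",
    max_tries: int = 1000,
) -> tuple[GroundTruth, SampledNetwork, int]:
    """Generate truth and sample jointly, regenerating on undersized samples.

    A sample of fewer than four agents discards the whole draw — network,
    weights and trajectory — and starts over with fresh randomness.  Returns
    (truth, sample, number of rejected draws).
    """
    rejections = 0
    for _ in range(max_tries):
        truth = generate_ground_truth(
            N, d, rng, target_self_weight=target_self_weight, kappa=kappa,
            spec=spec, n_steps=n_steps, neighbor_split=neighbor_split,
            max_tries=max_tries,
        )
        try:
            sample = snowball_sample(truth.adjacency, p, rng)
        except SampleRejectedError:
            rejections += 1
            continue
        return truth, sample, rejections
    raise GenerationError(
        f"no admissible sample in {max_tries} tries (N={N}, d={d}, p={p})"
    )


def build_adjacency_variety(
    truth_adjacency,
    sample: SampledNetwork,
    kind: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Construct one adjacency-matrix variety over the sampled agents.

    ``correct`` reduces the true adjacency to the sampled agents.  ``build``
    drops all same-wave links from the correct matrix and keeps, for each
    second-wave agent, a single uniformly chosen link to a sampled first-wave
    true neighbour (the recruiter is always a candidate, so the recruitment
    tree survives).  ``remove`` adds every link among wave-1 and wave-2
    agents to the correct matrix, leaving the seed's row as observed — the
    seed is assumed unlinked to anyone beyond those he named.  ``complete``
    is all ones.  All varieties carry unit diagonals.
    """
    if kind not in ADJACENCY_KINDS:
        raise ValueError(f"unknown adjacency kind {kind!r}")
    A = validate_adjacency(truth_adjacency)
    ids = list(sample.sampled_ids)
    M = len(ids)
    correct = A[np.ix_(ids, ids)].copy()
    np.fill_diagonal(correct, 1.0)
    if kind == "correct":
        return correct
    if kind == "complete":
        return np.ones((M, M))
    waves = sample.waves()
    if kind == "remove":
        out = correct.copy()
        nonseed = np.nonzero(waves >= 1)[0]
        out[np.ix_(nonseed, nonseed)] = 1.0
        np.fill_diagonal(out, 1.0)
        return out
    # build
    if kind == "build" and rng is None:
        raise ValueError("the build variety requires an rng for link selection")
    out = correct.copy()
    same_wave = waves[:, None] == waves[None, :]
    out[same_wave] = 0.0
    np.fill_diagonal(out, 1.0)
    wave1 = np.nonzero(waves == 1)[0]
    for k in np.nonzero(waves == 2)[0]:
        linked = wave1[out[k, wave1] == 1.0]
        if linked.size == 0:  # recruiter is always a sampled wave-1 neighbour
            raise RuntimeError("second-wave agent with no sampled recruiter")
        keep = int(linked[rng.integers(linked.size)])
        out[k, wave1] = 0.0
        out[wave1, k] = 0.0
        out[k, keep] = 1.0
        out[keep, k] = 1.0
    return out
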