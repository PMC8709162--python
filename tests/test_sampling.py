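"""Network generation, snowball sampling, and adjacency varieties."""

import numpy as np
import pytest

from degrootfit import (
    SampledNetwork,
    SampleRejectedError,
    build_adjacency_variety,
    generate_er_network,
    generate_initial_opinions,
    generate_weight_matrix,
    snowball_sample,
)
from degrootfit.dynamics import validate_adjacency
from degrootfit.sampling import ADJACENCY_KINDS


class TestErNetwork:
    def test_max_degree_gives_complete_graph(self, rng):
        A = generate_er_network(10, 9, rng)
        np.testing.assert_array_equal(A, np.ones((10, 10)))

    def test_deterministic_under_fixed_seed(self):
        A1 = generate_er_network(10, 5, np.random.default_rng(7))
        A2 = generate_er_network(10, 5, np.random.default_rng(7))
        np.testing.assert_array_equal(A1, A2)

    def test_valid_connected_adjacency(self, rng):
        import networkx as nx

        for _ in range(20):
            A = generate_er_network(12, 3, rng)
            validate_adjacency(A)
            G = nx.from_numpy_array(A - np.eye(12))
            assert nx.is_connected(G)

    def test_mean_degree_matches_target(self, rng):
        # accepted graphs keep expected degree near d (mild rejection bias)
        degs = []
        for _ in range(400):
            A = generate_er_network(50, 5, rng)
            degs.append((A.sum() - 50) / 50)
        assert np.mean(degs) == pytest.approx(5.0, abs=0.15)

    def test_degree_out_of_range(self, rng):
        with pytest.raises(ValueError):
            generate_er_network(10, 10, rng)


class TestWeightGeneration:
    def test_isolated_agents_forced_to_self_weight(self, rng):
        W = generate_weight_matrix(np.eye(4), rng)
        np.testing.assert_array_equal(W, np.eye(4))

    def test_rows_sum_to_one_and_respect_zeros(self, rng):
        for _ in range(20):
            A = generate_er_network(8, 3, rng)
            W = generate_weight_matrix(A, rng)
            np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(W[A == 0] == 0)

    def test_mean_self_weight_matches_beta_target(self, rng):
        # >= 1e4 Beta(2, 2) draws across many complete graphs
        A = np.ones((100, 100))
        draws = [np.diag(generate_weight_matrix(A, rng)) for _ in range(100)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_dirichlet_split_also_feasible(self, rng):
        A = generate_er_network(8, 4, rng)
        W = generate_weight_matrix(A, rng, neighbor_split="dirichlet")
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(W[A == 0] == 0)


def test_initial_opinions_uniform_and_reproducible():
    x1 = generate_initial_opinions(10_000, np.random.default_rng(3))
    x2 = generate_initial_opinions(10_000, np.random.default_rng(3))
    np.testing.assert_array_equal(x1, x2)
    assert np.all((x1 >= 0) & (x1 <= 1))
    assert x1.mean() == pytest.approx(0.5, abs=0.02)
    assert x1.var() == pytest.approx(1 / 12, abs=0.01)


def star_adjacency(n_leaves):
    A = np.eye(n_leaves + 1)
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    return A


class TestSnowball:
    def test_guaranteed_recruitment_covers_two_hop_ball(self, rng):
        for _ in range(20):
            A = generate_er_network(15, 3, rng)
            sample = snowball_sample(A, 1.0, rng)
            off = A - np.eye(15)
            dist1 = off[sample.seed_id] > 0
            dist2 = (off @ off)[sample.seed_id] > 0
            ball = {sample.seed_id} | set(np.nonzero(dist1 | dist2)[0])
            assert set(sample.sampled_ids) == ball

    def test_star_graph_all_wave_one(self, rng):
        sample = snowball_sample(star_adjacency(6), 1.0, rng)
        assert sample.seed_id == 0
        assert sorted(sample.sampled_ids) == list(range(7))
        assert all(sample.wave_of[i] == 1 for i in range(1, 7))

    def test_deterministic_under_fixed_seed(self, rng):
        A = generate_er_network(20, 4, rng)
        s1 = snowball_sample(A, 0.5, np.random.default_rng(11))
        s2 = snowball_sample(A, 0.5, np.random.default_rng(11))
        assert s1 == s2

    def test_small_samples_rejected(self, rng):
        # 3-agent path: at most 3 agents can ever be sampled
        A = np.eye(3)
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1.0
        with pytest.raises(SampleRejectedError):
            snowball_sample(A, 1.0, rng)

    def test_one_bernoulli_trial_per_contacted_agent(self, rng):
        class CountingRng:
            def __init__(self, inner):
                self.inner = inner
                self.trials = 0

            def random(self):
                self.trials += 1
                return self.inner.random()

            def integers(self, *a, **kw):
                return self.inner.integers(*a, **kw)

        for _ in range(10):
            A = generate_er_network(15, 4, rng)
            counter = CountingRng(np.random.default_rng(5))
            try:
                sample = snowball_sample(A, 0.6, counter)
            except SampleRejectedError:
                continue
            off = A - np.eye(15)
            wave1 = [i for i in sample.sampled_ids if sample.wave_of[i] == 1]
            contacted = set(np.nonzero(off[sample.seed_id])[0])
            for r in wave1:
                contacted |= set(np.nonzero(off[r])[0])
            contacted.discard(sample.seed_id)
            assert counter.trials == len(contacted)

    def test_recruitment_edges_form_tree_from_true_links(self, rng):
        A = generate_er_network(20, 5, rng)
        sample = snowball_sample(A, 0.7, rng)
        assert sample.wave_of[sample.seed_id] == 0
        recruits = {b: a for a, b in sample.recruitment_edges}
        for agent in sample.sampled_ids:
            if agent == sample.seed_id:
                continue
            recruiter = recruits[agent]
            assert A[recruiter, agent] == 1.0
            assert sample.wave_of[recruiter] == sample.wave_of[agent] - 1


def path_sample():
    """seed - a - b path, fully sampled (a wave 1, b wave 2)."""
    A = np.eye(5)
    links = [(0, 1), (1, 2), (0, 3), (3, 4)]
    for i, j in links:
        A[i, j] = A[j, i] = 1.0
    sample = SampledNetwork(
        sampled_ids=(0, 1, 3, 2, 4),
        wave_of={0: 0, 1: 1, 3: 1, 2: 2, 4: 2},
        recruitment_edges=((0, 1), (0, 3), (1, 2), (3, 4)),
        seed_id=0,
    )
    return A, sample


class TestAdjacencyVarieties:
    def test_complete_is_all_ones(self, rng):
        A, sample = path_sample()
        out = build_adjacency_variety(A, sample, "complete")
        np.testing.assert_array_equal(out, np.ones((5, 5)))

    def test_build_on_tree_equals_correct(self, rng):
        # no same-wave true links; each wave-2 agent has a single recruiter
        A, sample = path_sample()
        build = build_adjacency_variety(A, sample, "build", rng)
        correct = build_adjacency_variety(A, sample, "correct")
        np.testing.assert_array_equal(build, correct)

    def test_remove_adds_all_nonseed_links_only(self, rng):
        A, sample = path_sample()
        out = build_adjacency_variety(A, sample, "remove")
        expected = np.ones((5, 5))
        # seed (index 0 in sampled order) keeps only its true links (to 1, 3)
        expected[0] = [1, 1, 1, 0, 0]
        expected[:, 0] = expected[0]
        np.testing.assert_array_equal(out, expected)

    def test_entrywise_ordering_on_random_samples(self, rng):
        done = 0
        while done < 30:
            A = generate_er_network(20, 4, rng)
            try:
                sample = snowball_sample(A, 0.6, rng)
            except SampleRejectedError:
                continue
            done += 1
            mats = {
                kind: build_adjacency_variety(A, sample, kind, rng)
                for kind in ADJACENCY_KINDS
            }
            assert np.all(mats["build"] <= mats["correct"])
            assert np.all(mats["correct"] <= mats["remove"])
            assert np.all(mats["remove"] <= mats["complete"])
            for m in mats.values():
                np.testing.assert_array_equal(np.diag(m), 1.0)
                np.testing.assert_array_equal(m, m.T)

    def test_build_keeps_recruitment_tree(self, rng):
        done = 0
        while done < 20:
            A = generate_er_network(20, 5, rng)
            try:
                sample = snowball_sample(A, 0.6, rng)
            except SampleRejectedError:
                continue
            done += 1
            build = build_adjacency_variety(A, sample, "build", rng)
            pos = {a: k for k, a in enumerate(sample.sampled_ids)}
            wave2 = [a for a in sample.sampled_ids if sample.wave_of[a] == 2]
            wave1 = [a for a in sample.sampled_ids if sample.wave_of[a] == 1]
            # seed-wave1 links all present; each wave-2 agent exactly one link
            for a in wave1:
                assert build[pos[sample.seed_id], pos[a]] == 1.0
            for b in wave2:
                row = build[pos[b]]
                assert row[[pos[a] for a in wave1]].sum() == 1.0

    def test_unknown_kind(self, rng):
        A, sample = path_sample()
        with pytest.raises(ValueError):
            build_adjacency_variety(A, sample, "bogus")
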