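import numpy as np
import pytest
from conftest import random_contact_graph
from oracles import brute_transition

from profun.errors import ConfigError
from profun.node2vec import (
    EmbeddingTable,
    StrandedWalkerError,
    WalkConfig,
    alpha_pq,
    embed_protein,
    generate_walks,
    train_embeddings,
    transition_distribution,
)
from profun.structure_graph import ContactGraph

PATH_GRAPH = ContactGraph("path", 3, {(0, 1), (1, 2)}, has_self_loops=False)


class TestAlpha:
    def test_return_case(self):
        assert alpha_pq(0, 0.8, 1.2) == pytest.approx(1.25)

    def test_stay_case(self):
        assert alpha_pq(1, 0.8, 1.2) == 1.0
        assert alpha_pq(1, 5.0, 0.1) == 1.0

    def test_explore_case(self):
        assert alpha_pq(2, 0.8, 1.2) == pytest.approx(1 / 1.2)

    def test_unbiased_limit(self):
        assert all(alpha_pq(d, 1.0, 1.0) == 1.0 for d in (0, 1, 2))

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            alpha_pq(3, 1.0, 1.0)


class TestTransitionDistribution:
    def test_path_graph_hand_values(self):
        cfg = WalkConfig(p=0.8, q=1.2)
        dist = transition_distribution(PATH_GRAPH, 0, 1, cfg)
        assert dist[0] == pytest.approx(0.6, abs=1e-12)
        assert dist[2] == pytest.approx(0.4, abs=1e-12)

    def test_triangle_uniform_when_unbiased(self):
        tri = ContactGraph("tri", 3, {(0, 1), (0, 2), (1, 2)}, has_self_loops=False)
        dist = transition_distribution(tri, 0, 1, WalkConfig(p=1.0, q=1.0))
        assert dist == {0: pytest.approx(0.5), 2: pytest.approx(0.5)}

    def test_sums_to_one(self, rng):
        cfg = WalkConfig(p=0.7, q=1.9)
        for seed in range(20):
            g = random_contact_graph(np.random.default_rng(seed), 8)
            for (i, j) in list(g.edges)[:5]:
                if i == j:
                    continue
                dist = transition_distribution(g, i, j, cfg)
                assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_first_step_weight_proportional(self):
        g = ContactGraph(
            "w", 3, {(0, 1), (0, 2)}, has_self_loops=False,
            edge_weights={(0, 1): 3.0, (0, 2): 1.0},
        )
        dist = transition_distribution(g, None, 0, WalkConfig())
        assert dist[1] == pytest.approx(0.75)
        assert dist[2] == pytest.approx(0.25)

    def test_oracle_equivalence_random_graphs(self):
        cfg = WalkConfig(p=0.8, q=1.2)
        for seed in range(30):
            g_rng = np.random.default_rng(seed)
            g = random_contact_graph(g_rng, int(g_rng.integers(3, 12)))
            A = g.adjacency(self_loops=False)
            W = A.copy()
            for t in range(g.n_nodes):
                for v in g.neighbors(t):
                    got = transition_distribution(g, t, v, cfg)
                    want = brute_transition(A, W, t, v, cfg.p, cfg.q)
                    assert got.keys() == want.keys()
                    for x in want:
                        assert got[x] == pytest.approx(want[x], abs=1e-12)

    def test_self_loops_excluded_from_walks(self):
        g = ContactGraph(
            "sl", 3, {(0, 0), (1, 1), (2, 2), (0, 1), (1, 2)}, has_self_loops=True
        )
        dist = transition_distribution(g, 0, 1, WalkConfig())
        assert 1 not in dist

    def test_non_adjacent_prev_rejected(self):
        with pytest.raises(ValueError, match="not adjacent"):
            transition_distribution(PATH_GRAPH, 2, 0, WalkConfig())


class TestGenerateWalks:
    def test_walk_length_one(self):
        cfg = WalkConfig(walk_length=1, walks_per_node=3)
        walks = generate_walks(PATH_GRAPH, cfg)
        assert sorted(walks) == [[0], [0], [0], [1], [1], [1], [2], [2], [2]]

    def test_determinism(self):
        cfg = WalkConfig(walks_per_node=4, walk_length=10, seed=42)
        assert generate_walks(PATH_GRAPH, cfg) == generate_walks(PATH_GRAPH, cfg)

    def test_counts_and_lengths(self, rng):
        g = random_contact_graph(rng, 9)
        cfg = WalkConfig(walks_per_node=3, walk_length=7)
        walks = generate_walks(g, cfg)
        assert len(walks) == 27
        assert all(len(w) == 7 for w in walks)

    def test_stranded_walker_truncates(self):
        g = ContactGraph("iso", 2, {(0, 0), (1, 1)}, has_self_loops=True)
        walks = generate_walks(g, WalkConfig(walks_per_node=1, walk_length=5))
        assert walks == [[0], [1]]

    def test_monte_carlo_matches_exact_distribution(self):
        cfg = WalkConfig(p=0.8, q=1.2, seed=0)
        exact = transition_distribution(PATH_GRAPH, 0, 1, cfg)
        n = 10_000
        rng = np.random.default_rng(1)
        counts = {0: 0, 2: 0}
        nbrs = np.array([0, 2])
        probs = np.array([exact[0], exact[2]])
        for _ in range(n):
            counts[int(rng.choice(nbrs, p=probs))] += 1
        for x in (0, 2):
            se = np.sqrt(exact[x] * (1 - exact[x]) / n)
            assert abs(counts[x] / n - exact[x]) < 3 * se + 1e-9


class TestTrainEmbeddings:
    def test_dimension(self):
        walks = [[0, 1, 2, 1, 0]] * 10
        table = train_embeddings(walks, WalkConfig(embedding_dim=7, epochs=1))
        assert table.dim == 7
        assert all(len(v) == 7 for v in table.vectors.values())

    def test_determinism(self):
        walks = generate_walks(PATH_GRAPH, WalkConfig(walks_per_node=5, walk_length=10))
        cfg = WalkConfig(embedding_dim=8, epochs=2, seed=3)
        t1 = train_embeddings(walks, cfg)
        t2 = train_embeddings(walks, cfg)
        assert all(np.array_equal(t1.vectors[i], t2.vectors[i]) for i in t1.vectors)

    def test_missing_node_zero_vector_with_warning(self):
        walks = [[0, 1, 0, 1]] * 5
        with pytest.warns(UserWarning, match="absent"):
            table = train_embeddings(
                walks, WalkConfig(embedding_dim=4, epochs=1), n_nodes=3
            )
        assert np.array_equal(table.vectors[2], np.zeros(4))

    def test_two_cliques_community_structure(self):
        edges = {(i, j) for i in range(6) for j in range(i + 1, 6)}
        edges |= {(i, j) for i in range(6, 12) for j in range(i + 1, 12)}
        edges.add((5, 6))
        g = ContactGraph("cl", 12, edges, has_self_loops=False)
        cfg = WalkConfig(
            walks_per_node=10, walk_length=30, embedding_dim=16,
            context_window=5, epochs=5, seed=0,
        )
        M = embed_protein(g, cfg).as_matrix(12)
        M = M / np.linalg.norm(M, axis=1, keepdims=True)
        S = M @ M.T
        intra = np.mean(
            [S[i, j] for i in range(6) for j in range(6) if i != j]
            + [S[i, j] for i in range(6, 12) for j in range(6, 12) if i != j]
        )
        inter = np.mean([S[i, j] for i in range(6) for j in range(6, 12)])
        assert intra > inter


class TestEmbedProtein:
    def test_single_node_graph(self):
        g = ContactGraph("one", 1, {(0, 0)}, has_self_loops=True)
        table = embed_protein(g, WalkConfig(embedding_dim=5, epochs=1))
        assert np.all(np.isfinite(table.vectors[0]))

    def test_ring_graph_all_finite(self):
        edges = {(i, (i + 1) % 20) for i in range(19)} | {(0, 19)}
        edges = {(min(a, b), max(a, b)) for a, b in edges}
        g = ContactGraph("ring", 20, edges, has_self_loops=False)
        cfg = WalkConfig(walks_per_node=3, walk_length=15, embedding_dim=8, epochs=2, seed=0)
        table = embed_protein(g, cfg)
        assert len(table.vectors) == 20
        assert all(np.all(np.isfinite(v)) for v in table.vectors.values())

    def test_barbell_bridge_between_cliques(self):
        m = 5
        edges = {(i, j) for i in range(m) for j in range(i + 1, m)}
        hi = {(i, j) for i in range(m + 1, 2 * m + 1) for j in range(i + 1, 2 * m + 1)}
        edges |= hi
        bridge = m  # node m connects the two cliques
        edges |= {(m - 1, bridge), (bridge, m + 1)}
        g = ContactGraph("bar", 2 * m + 1, edges, has_self_loops=False)
        cfg = WalkConfig(
            walks_per_node=12, walk_length=30, embedding_dim=16,
            context_window=5, epochs=5, seed=0,
        )
        M = embed_protein(g, cfg).as_matrix(2 * m + 1)
        Mn = M / np.linalg.norm(M, axis=1, keepdims=True)
        c1 = Mn[:m].mean(axis=0)
        c2 = Mn[m + 1 :].mean(axis=0)
        b = Mn[bridge]

        def cos(a, bb):
            return float(a @ bb / (np.linalg.norm(a) * np.linalg.norm(bb)))

        # bridge is less extreme than either clique centre: its similarity to
        # the far clique exceeds the cliques' similarity to each other
        assert min(cos(b, c1), cos(b, c2)) > cos(c1, c2)


class TestEmbeddingTableIO:
    def test_round_trip(self, tmp_path):
        table = EmbeddingTable("t", {0: np.array([1.0, -2.5]), 1: np.array([0.25, 3.0])})
        path = tmp_path / "emb.tsv"
        with open(path, "w") as fh:
            table.write(fh)
        with open(path) as fh:
            back = EmbeddingTable.read(fh, "t")
        assert all(np.allclose(back.vectors[i], table.vectors[i]) for i in (0, 1))


class TestWalkConfigValidation:
    def test_nonpositive_pq_rejected(self):
        with pytest.raises(ConfigError):
            WalkConfig(p=0.0)
        with pytest.raises(ConfigError):
            WalkConfig(q=-1.0)

    def test_zero_counts_rejected(self):
        with pytest.raises(ConfigError):
            WalkConfig(walk_length=0)
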