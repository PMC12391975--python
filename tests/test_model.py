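import numpy as np
import pytest
from conftest import random_dense_adjacency
from oracles import brute_topk

from profun.autodiff import Tensor
from profun.errors import ConfigError
from profun.model import (
    GraphBatch,
    Model,
    ModelConfig,
    bce_loss,
    graph_conv,
    mix_pool,
    norm_adjacency,
    sag_pool,
)


def small_config(**kw):
    defaults = dict(
        n_labels=4, node_feature_dim=6, seq_embedding_dim=10,
        hidden_dim=16, n_blocks=3, transformer_layers=2, attention_heads=4,
        dropout=0.0, seed=0,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def make_batch(rng, n_graphs=3, nodes=10, dim=6):
    adjs = [random_dense_adjacency(rng, nodes) for _ in range(n_graphs)]
    feats = [rng.standard_normal((nodes, dim)) for _ in range(n_graphs)]
    return GraphBatch([f"p{i}" for i in range(n_graphs)], adjs, feats)


class TestGraphConv:
    def test_single_node_fixed_point(self):
        H = Tensor(np.array([[2.0, -1.0]]))
        out = graph_conv(H, norm_adjacency(np.array([[1.0]])), Tensor(np.eye(2)),
                         activation="identity")
        assert np.allclose(out.data, H.data)

    def test_two_node_hand_value(self):
        # joined pair with self-loops: normalized Ã = [[1/2,1/2],[1/2,1/2]]
        A = np.array([[1.0, 1.0], [1.0, 1.0]])
        H = Tensor(np.array([[1.0], [0.0]]))
        out = graph_conv(H, norm_adjacency(A), Tensor(np.array([[1.0]])),
                         activation="identity")
        assert np.allclose(out.data, [[0.5], [0.5]])

    def test_permutation_equivariance(self, rng):
        n, d = 8, 5
        A = random_dense_adjacency(rng, n)
        H = rng.standard_normal((n, d))
        W = Tensor(rng.standard_normal((d, 3)))
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        out = graph_conv(Tensor(H), norm_adjacency(A), W).data
        out_p = graph_conv(Tensor(P @ H), norm_adjacency(P @ A @ P.T), W).data
        assert np.allclose(out_p, P @ out, atol=1e-10)

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError, match="graph_conv"):
            graph_conv(Tensor(np.ones((2, 3))), np.eye(2), Tensor(np.ones((4, 2))))


class TestSagPool:
    def _thetas(self, rng, d):
        return Tensor(rng.standard_normal((d, 1))), Tensor(rng.standard_normal((d, 1)))

    def test_ratio_one_keeps_all_and_gates(self, rng):
        n, d = 6, 4
        A = random_dense_adjacency(rng, n)
        X = Tensor(rng.standard_normal((n, d)))
        t1, t2 = self._thetas(rng, d)
        X_out, A_out, kept, y = sag_pool(X, A, 1.0, t1, t2)
        assert list(kept) == list(range(n))
        assert np.allclose(X_out.data, X.data * y.data)
        assert np.array_equal(A_out, A)

    def test_topk_count_and_selection(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            A = random_dense_adjacency(rng, n)
            X = Tensor(rng.standard_normal((n, 5)))
            t1, t2 = self._thetas(rng, 5)
            ratio = float(rng.uniform(0.2, 1.0))
            X_out, A_out, kept, y = sag_pool(X, A, ratio, t1, t2)
            k = int(np.ceil(ratio * n))
            assert len(kept) == k
            assert list(kept) == brute_topk(y.data[:, 0], k)
            assert np.array_equal(A_out, A[np.ix_(kept, kept)])

    def test_known_scores_pick_top_three(self):
        # 4 nodes, ratio 0.75 -> keep ceil(3) = 3 highest scores
        y = np.array([0.9, 0.5, 0.1, 0.7])
        assert brute_topk(y, int(np.ceil(0.75 * 4))) == [0, 1, 3]

    def test_single_node(self, rng):
        A = np.array([[1.0]])
        X = Tensor(rng.standard_normal((1, 4)))
        t1, t2 = self._thetas(rng, 4)
        X_out, A_out, kept, _ = sag_pool(X, A, 0.5, t1, t2)
        assert list(kept) == [0]
        assert A_out.shape == (1, 1)


class TestMixPool:
    def test_single_node(self):
        v = np.array([[1.0, -2.0, 3.0]])
        out = mix_pool(Tensor(v)).data
        assert np.allclose(out, [1.0, -2.0, 3.0, 1.0, -2.0, 3.0])

    def test_hand_value(self):
        out = mix_pool(Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))).data
        assert np.allclose(out, [0.5, 0.5, 1.0, 1.0])

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((7, 4))
        perm = rng.permutation(7)
        assert np.allclose(mix_pool(Tensor(X)).data, mix_pool(Tensor(X[perm])).data)

    def test_empty_graph_error(self):
        with pytest.raises(ValueError, match="empty"):
            mix_pool(Tensor(np.zeros((0, 3))))


class TestConvPoolBlock:
    def test_batch_independence_and_identical_graphs(self, rng):
        cfg = small_config()
        m = Model(cfg)
        A = random_dense_adjacency(rng, 9)
        X = rng.standard_normal((9, cfg.node_feature_dim))
        batch = GraphBatch(["a", "b"], [A, A.copy()], [X, X.copy()])
        seq_row = rng.standard_normal(cfg.seq_embedding_dim)
        seq = np.vstack([seq_row, seq_row])
        out = m.forward(batch, seq).data
        assert np.allclose(out[0], out[1])

    def test_node_reduction_per_block(self, rng):
        cfg = small_config(sag_ratio=0.5)
        m = Model(cfg)
        X, A = Tensor(rng.standard_normal((8, cfg.node_feature_dim))), random_dense_adjacency(rng, 8)
        X1, A1, r = m.conv_pool_block(0, X, A)
        assert X1.shape[0] == 4  # ceil(0.5 * 8)
        assert A1.shape == (4, 4)
        assert r.shape == (2 * cfg.hidden_dim,)

    def test_batch_of_one_equals_unbatched(self, rng):
        cfg = small_config()
        m = Model(cfg)
        A = random_dense_adjacency(rng, 10)
        X = rng.standard_normal((10, cfg.node_feature_dim))
        seq = rng.standard_normal((1, cfg.seq_embedding_dim))
        single = m.forward(GraphBatch(["a"], [A], [X]), seq).data
        batch3 = make_batch(rng, 3, 10, cfg.node_feature_dim)
        batch3.adjacencies[1] = A
        batch3.features[1] = X
        seq3 = np.vstack([rng.standard_normal((1, cfg.seq_embedding_dim)), seq,
                          rng.standard_normal((1, cfg.seq_embedding_dim))])
        multi = m.forward(batch3, seq3).data
        assert np.allclose(single[0], multi[1], atol=1e-6)


class TestForward:
    def test_output_shape_and_range(self, rng):
        cfg = small_config()
        m = Model(cfg)
        batch = make_batch(rng)
        seq = rng.standard_normal((3, cfg.seq_embedding_dim))
        out = m.forward(batch, seq).data
        assert out.shape == (3, cfg.n_labels)
        assert out.min() >= 0 and out.max() <= 1

    def test_eval_determinism(self, rng):
        cfg = small_config(dropout=0.3)
        m = Model(cfg)
        batch = make_batch(rng)
        seq = rng.standard_normal((3, cfg.seq_embedding_dim))
        assert np.array_equal(
            m.forward(batch, seq, train=False).data,
            m.forward(batch, seq, train=False).data,
        )

    def test_batch_permutation_permutes_rows(self, rng):
        cfg = small_config()
        m = Model(cfg)
        batch = make_batch(rng, 4)
        seq = rng.standard_normal((4, cfg.seq_embedding_dim))
        out = m.forward(batch, seq).data
        perm = [2, 0, 3, 1]
        batch_p = GraphBatch(
            [batch.protein_ids[i] for i in perm],
            [batch.adjacencies[i] for i in perm],
            [batch.features[i] for i in perm],
        )
        out_p = m.forward(batch_p, seq[perm]).data
        assert np.allclose(out_p, out[perm], atol=1e-10)

    def test_mismatched_seq_embeddings_error(self, rng):
        cfg = small_config()
        m = Model(cfg)
        batch = make_batch(rng)
        with pytest.raises(ValueError, match="seq_embeddings"):
            m.forward(batch, np.zeros((3, cfg.seq_embedding_dim + 1)))

    def test_gradient_reaches_every_parameter(self, rng):
        cfg = small_config()
        m = Model(cfg)
        batch = make_batch(rng, 4)
        seq = rng.standard_normal((4, cfg.seq_embedding_dim))
        y = (rng.random((4, cfg.n_labels)) < 0.5).astype(float)
        m.zero_grad()
        bce_loss(m.forward(batch, seq), y).backward()
        dead = [
            k for k, t in m.params.items()
            if t.grad is None or float(np.abs(t.grad).max()) == 0.0
        ]
        assert dead == []


class TestStateIO:
    def test_save_load_round_trip(self, rng, tmp_path):
        cfg = small_config()
        m = Model(cfg)
        batch = make_batch(rng)
        seq = rng.standard_normal((3, cfg.seq_embedding_dim))
        out = m.forward(batch, seq).data
        path = str(tmp_path / "model.npz")
        m.save(path)
        m2 = Model.load(path)
        assert m2.config == cfg
        assert np.array_equal(m2.forward(batch, seq).data, out)

    def test_load_state_shape_check(self):
        m = Model(small_config())
        state = m.state_dict()
        state["head0.w"] = state["head0.w"][:, :1]
        with pytest.raises(ValueError, match="shape"):
            m.load_state(state)


class TestConfigValidation:
    def test_heads_divide_hidden(self):
        with pytest.raises(ConfigError):
            small_config(hidden_dim=30, attention_heads=8)

    def test_ratio_bounds(self):
        with pytest.raises(ConfigError):
            small_config(sag_ratio=0.0)

    def test_defaults_match_architecture(self):
        cfg = ModelConfig(n_labels=2, node_feature_dim=4, seq_embedding_dim=8)
        assert cfg.n_blocks == 6
        assert cfg.sag_ratio == 0.75
        assert cfg.transformer_layers == 3
        assert cfg.attention_heads == 8
        assert cfg.classifier_layers == 3
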