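"""Hierarchical graph-pooling network for multilabel GO classification.

Architecture: a stack of ConvPoolBlocks — a 3-layer spectral graph
convolution, self-attention top-k pooling at a fixed ratio, and a mix-pool
readout (mean ∥ max) — whose per-block readouts are aggregated and fused
with the global sequence embedding, passed through a small transformer
encoder over three tokens (graph readout, sequence embedding, learned
classification token), and classified by a 3-layer fully connected head
with logistic outputs.

Graph convolution follows the symmetric normalisation
``H' = act(D̃^{-1/2} Ã D̃^{-1/2} H W)`` with Ã the self-loop adjacency.
Self-attention scores are two independent passes of
``z = tanh(D̃^{-1/2} Ã D̃^{-1/2} X θ)`` averaged per node; the top
``ceil(ratio · N)`` nodes are kept (ties to the lower index), features are
gated by their scores and the adjacency is restricted to the kept nodes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
import numpy as np

from .autodiff import Tensor, concat, gather_rows
from .errors import ConfigError

__all__ = [
    "ModelConfig",
    "GraphBatch",
    "norm_adjacency",
    "graph_conv",
    "sag_pool",
    "mix_pool",
    "Model",
]


@dataclass(frozen=True)
class ModelConfig:
    n_labels: int
    node_feature_dim: int
    seq_embedding_dim: int
    n_blocks: int = 6
    hidden_dim: int = 32
    sag_ratio: float = 0.75
    transformer_layers: int = 3
    attention_heads: int = 8
    classifier_layers: int = 3
    dropout: float = 0.2
    use_onehot_node_features: bool = False
    readout_agg: str = "sum"  # sum | concat
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.attention_heads != 0:
            raise ConfigError("hidden_dim must be divisible by attention_heads")
        if not (0 < self.sag_ratio <= 1):
            raise ConfigError("sag_ratio must be in (0, 1]")
        if not (0 <= self.dropout < 1):
            raise ConfigError("dropout must be in [0, 1)")
        if self.n_labels < 1:
            raise ConfigError("n_labels must be >= 1")
        if self.readout_agg not in ("sum", "concat"):
            raise ConfigError("readout_agg must be 'sum' or 'concat'")


@dataclass
class GraphBatch:
    """Per-protein adjacency (with self-loops) and node feature matrices."""

    protein_ids: list[str]
    adjacencies: list[np.ndarray]  # each (N_i, N_i), symmetric, unit diagonal
    features: list[np.ndarray]  # each (N_i, node_feature_dim)

    def __post_init__(self) -> None:
        for pid, A, X in zip(self.protein_ids, self.adjacencies, self.features):
            if A.shape[0] != A.shape[1] or A.shape[0] != X.shape[0]:
                raise ValueError(f"{pid}: adjacency/feature shape mismatch")
            if not np.allclose(A, A.T):
                raise ValueError(f"{pid}: adjacency not symmetric")

    def __len__(self) -> int:
        return len(self.protein_ids)


def norm_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalisation ``D^{-1/2} A D^{-1/2}``."""
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, deg, 1.0) ** -0.5
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def graph_conv(
    H: Tensor,
    A_hat: np.ndarray,
    W: Tensor,
    activation: str = "relu",
    bias: Tensor | None = None,
) -> Tensor:
    """One spectral graph-convolution layer on a pre-normalised adjacency."""
    if H.shape[1] != W.shape[0]:
        raise ValueError(
            f"graph_conv: feature dim {H.shape[1]} does not match weight "
            f"input dim {W.shape[0]}"
        )
    out = Tensor(A_hat) @ (H @ W)
    if bias is not None:
        out = out + bias
    if activation == "relu":
        return out.relu()
    if activation == "tanh":
        return out.tanh()
    if activation in (None, "identity"):
        return out
    raise ValueError(f"unknown activation {activation!r}")


def sag_pool(
    X: Tensor,
    A: np.ndarray,
    ratio: float,
    theta1: Tensor,
    theta2: Tensor,
) -> tuple[Tensor, np.ndarray, np.ndarray, Tensor]:
    """Self-attention top-k pooling.

    Returns ``(X_out, A_out, kept_indices, scores)`` where scores are the
    per-node means of the two attention passes (before selection).
    """
    A_hat = norm_adjacency(A)
    z1 = graph_conv(X, A_hat, theta1, activation="tanh")
    z2 = graph_conv(X, A_hat, theta2, activation="tanh")
    y = (z1 + z2) * 0.5  # (N, 1)
    n = X.shape[0]
    k = int(np.ceil(ratio * n))
    order = np.lexsort((np.arange(n), -y.data[:, 0]))  # score desc, index asc
    kept = np.sort(order[:k])
    X_out = gather_rows(X, kept) * gather_rows(y, kept)
    A_out = A[np.ix_(kept, kept)]
    return X_out, A_out, kept, y


def mix_pool(X: Tensor) -> Tensor:
    """Readout vector: mean over nodes concatenated with max over nodes."""
    if X.shape[0] == 0:
        raise ValueError("mix_pool: empty graph")
    return concat([X.mean(axis=0), X.max(axis=0)], axis=-1)


# ---------------------------------------------------------------------------
# parameters and forward pass


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    # rectifier-gain init keeps activation scale through deep conv stacks
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Model:
    """Learned parameters plus the forward pass; see module docstring."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        in_dim = config.node_feature_dim + (
            21 if config.use_onehot_node_features else 0
        )
        p: dict[str, Tensor] = {}

        def param(name: str, value: np.ndarray) -> None:
            p[name] = Tensor(value, requires_grad=True)

        for b in range(config.n_blocks):
            d0 = in_dim if b == 0 else h
            param(f"block{b}.conv0", _he(rng, d0, h))
            param(f"block{b}.conv0_b", np.zeros(h))
            param(f"block{b}.conv1", _he(rng, h, h))
            param(f"block{b}.conv1_b", np.zeros(h))
            param(f"block{b}.conv2", _he(rng, h, h))
            param(f"block{b}.conv2_b", np.zeros(h))
            param(f"block{b}.att0", _glorot(rng, h, 1))
            param(f"block{b}.att1", _glorot(rng, h, 1))

        readout_dim = 2 * h * (config.n_blocks if config.readout_agg == "concat" else 1)
        param("fuse.graph_w", _glorot(rng, readout_dim, h))
        param("fuse.graph_b", np.zeros(h))
        param("fuse.seq_w", _glorot(rng, config.seq_embedding_dim, h))
        param("fuse.seq_b", np.zeros(h))
        param("fuse.cls", rng.standard_normal(h) * 0.02)

        for l in range(config.transformer_layers):
            for name in ("q", "k", "v", "o"):
                param(f"tf{l}.{name}_w", _glorot(rng, h, h))
                if name != "k":  # key bias is softmax-invariant (zero gradient)
                    param(f"tf{l}.{name}_b", np.zeros(h))
            param(f"tf{l}.ff1_w", _glorot(rng, h, 4 * h))
            param(f"tf{l}.ff1_b", np.zeros(4 * h))
            param(f"tf{l}.ff2_w", _glorot(rng, 4 * h, h))
            param(f"tf{l}.ff2_b", np.zeros(h))
            for ln in ("ln1", "ln2"):
                param(f"tf{l}.{ln}_g", np.ones(h))
                param(f"tf{l}.{ln}_b", np.zeros(h))

        dims = [h] * config.classifier_layers + [config.n_labels]
        for l in range(config.classifier_layers):
            param(f"head{l}.w", _glorot(rng, dims[l], dims[l + 1]))
            param(f"head{l}.b", np.zeros(dims[l + 1]))

        self.params = p
        self._drop_rng = np.random.default_rng(config.seed + 1)

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path: str) -> None:
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: str) -> "Model":
        with np.load(path) as archive:
            cfg = ModelConfig(**json.loads(bytes(archive["__config__"]).decode()))
            model = cls(cfg)
            model.load_state(
                {k: archive[k] for k in archive.files if k != "__config__"}
            )
        return model

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    # -- building blocks ---------------------------------------------------

    def _dropout(self, x: Tensor, train: bool) -> Tensor:
        rate = self.config.dropout
        if not train or rate == 0.0:
            return x
        mask = (self._drop_rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(mask)

    def _layer_norm(self, x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + 1e-5) ** -0.5) * gamma + beta

    def conv_pool_block(
        self, block: int, X: Tensor, A: np.ndarray
    ) -> tuple[Tensor, np.ndarray, Tensor]:
        """One ConvPoolBlock: 3-layer GraphConv, SAGPool, mix-pool readout."""
        p = self.params
        A_hat = norm_adjacency(A)
        H = graph_conv(X, A_hat, p[f"block{block}.conv0"], bias=p[f"block{block}.conv0_b"])
        H = graph_conv(H, A_hat, p[f"block{block}.conv1"], bias=p[f"block{block}.conv1_b"])
        H = graph_conv(H, A_hat, p[f"block{block}.conv2"], bias=p[f"block{block}.conv2_b"])
        H, A_out, _, _ = sag_pool(
            H, A, self.config.sag_ratio,
            p[f"block{block}.att0"], p[f"block{block}.att1"],
        )
        return H, A_out, mix_pool(H)

    def _encode_graph(self, A: np.ndarray, X0: np.ndarray) -> Tensor:
        """Run all blocks on one protein; aggregate readouts."""
        X = Tensor(X0)
        A_cur = A
        readouts: list[Tensor] = []
        for b in range(self.config.n_blocks):
            X, A_cur, r = self.conv_pool_block(b, X, A_cur)
            readouts.append(r)
        if self.config.readout_agg == "concat":
            return concat(readouts, axis=-1)
        agg = readouts[0]
        for r in readouts[1:]:
            agg = agg + r
        return agg

    def _transformer(self, tokens: Tensor, train: bool) -> Tensor:
        """Post-LN multi-head self-attention encoder over (B, T, h) tokens."""
        cfg = self.config
        h = cfg.hidden_dim
        n_heads = cfg.attention_heads
        dk = h // n_heads
        B, T, _ = tokens.shape
        x = tokens
        for l in range(cfg.transformer_layers):
            p = self.params
            q = x @ p[f"tf{l}.q_w"] + p[f"tf{l}.q_b"]
            k = x @ p[f"tf{l}.k_w"]
            v = x @ p[f"tf{l}.v_w"] + p[f"tf{l}.v_b"]
            # (B, T, h) -> (B, heads, T, dk)
            q = q.reshape(B, T, n_heads, dk).swapaxes(1, 2)
            k = k.reshape(B, T, n_heads, dk).swapaxes(1, 2)
            v = v.reshape(B, T, n_heads, dk).swapaxes(1, 2)
            scores = (q @ k.swapaxes(-1, -2)) * (dk**-0.5)
            attn = scores.softmax(axis=-1)
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, T, h)
            ctx = ctx @ p[f"tf{l}.o_w"] + p[f"tf{l}.o_b"]
            x = self._layer_norm(
                x + self._dropout(ctx, train),
                p[f"tf{l}.ln1_g"], p[f"tf{l}.ln1_b"],
            )
            ff = (x @ p[f"tf{l}.ff1_w"] + p[f"tf{l}.ff1_b"]).relu()
            ff = ff @ p[f"tf{l}.ff2_w"] + p[f"tf{l}.ff2_b"]
            x = self._layer_norm(
                x + self._dropout(ff, train),
                p[f"tf{l}.ln2_g"], p[f"tf{l}.ln2_b"],
            )
        return x

    # -- forward -----------------------------------------------------------

    def forward_logits(
        self,
        batch: GraphBatch,
        seq_embeddings: np.ndarray,
        train: bool = False,
    ) -> Tensor:
        """Pre-sigmoid label scores, shape (len(batch), n_labels)."""
        cfg = self.config
        if seq_embeddings.shape != (len(batch), cfg.seq_embedding_dim):
            raise ValueError(
                f"seq_embeddings shape {seq_embeddings.shape} does not match "
                f"(batch={len(batch)}, dim={cfg.seq_embedding_dim})"
            )
        p = self.params
        readouts = [
            self._encode_graph(A, X)
            for A, X in zip(batch.adjacencies, batch.features)
        ]
        graph_mat = concat(
            [r.reshape(1, -1) for r in readouts], axis=0
        )  # (B, readout_dim)
        g_tok = graph_mat @ p["fuse.graph_w"] + p["fuse.graph_b"]
        s_tok = Tensor(seq_embeddings) @ p["fuse.seq_w"] + p["fuse.seq_b"]
        B = len(batch)
        cls_tok = p["fuse.cls"].reshape(1, -1) * Tensor(np.ones((B, 1)))
        tokens = concat(
            [
                g_tok.reshape(B, 1, cfg.hidden_dim),
                s_tok.reshape(B, 1, cfg.hidden_dim),
                cls_tok.reshape(B, 1, cfg.hidden_dim),
            ],
            axis=1,
        )
        encoded = self._transformer(tokens, train)
        # classification token output feeds the head
        x = gather_rows(
            encoded.reshape(B * 3, cfg.hidden_dim), np.arange(2, B * 3, 3)
        )
        for l in range(cfg.classifier_layers):
            x = x @ p[f"head{l}.w"] + p[f"head{l}.b"]
            if l < cfg.classifier_layers - 1:
                x = self._dropout(x.relu(), train)
        return x

    def forward(
        self,
        batch: GraphBatch,
        seq_embeddings: np.ndarray,
        train: bool = False,
    ) -> Tensor:
        """Per-protein per-label probabilities in [0, 1]."""
        return self.forward_logits(batch, seq_embeddings, train).sigmoid()


def bce_loss(probs: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean elementwise binary cross-entropy against {0,1} labels."""
    y = Tensor(np.asarray(labels, dtype=np.float64))
    one = Tensor(np.ones_like(probs.data))
    return -(
        y * (probs + eps).log() + (one - y) * (one - probs + eps).log()
    ).mean()
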