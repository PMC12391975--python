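"""Biased random-walk node embeddings for residue contact graphs.

Second-order walks controlled by a return parameter ``p`` and an in-out
parameter ``q`` (defaults 0.8 / 1.2): stepping from ``v`` after arriving
from ``t``, the unnormalised probability of moving to neighbour ``x`` is
``alpha_pq(d_tx) * w_vx`` where ``d_tx`` is the shortest-path distance from
``t`` to ``x`` (0, 1 or 2 for any neighbour of ``v``). Walk corpora are
embedded with skip-gram and negative sampling.

Self-loops are excluded from the walk graph — a self-step carries no
structural information and makes the distance cases ill-posed — but kept in
the adjacency used by downstream graph convolutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np

from .errors import ConfigError, ProfunError
from .structure_graph import ContactGraph

__all__ = [
    "WalkConfig",
    "EmbeddingTable",
    "alpha_pq",
    "transition_distribution",
    "generate_walks",
    "train_embeddings",
    "embed_protein",
]


class StrandedWalkerError(ProfunError):
    """Raised when a walk starts on a node with no non-self neighbours."""


@dataclass(frozen=True)
class WalkConfig:
    """Hyperparameters for walk generation and skip-gram training."""

    p: float = 0.8
    q: float = 1.2
    walks_per_node: int = 10
    walk_length: int = 80
    embedding_dim: int = 30
    context_window: int = 10
    negative_samples: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ConfigError("p and q must be positive")
        for name in (
            "walks_per_node",
            "walk_length",
            "embedding_dim",
            "context_window",
            "negative_samples",
            "epochs",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")


@dataclass
class EmbeddingTable:
    """Per-node embedding vectors for one protein graph."""

    protein_id: str
    vectors: dict[int, np.ndarray]

    @property
    def dim(self) -> int:
        return len(next(iter(self.vectors.values())))

    def as_matrix(self, n_nodes: int | None = None) -> np.ndarray:
        n = n_nodes if n_nodes is not None else max(self.vectors) + 1
        out = np.zeros((n, self.dim))
        for idx, vec in self.vectors.items():
            out[idx] = vec
        return out

    def write(self, sink: TextIO) -> None:
        for idx in sorted(self.vectors):
            vals = "\t".join(f"{v:.8g}" for v in self.vectors[idx])
            sink.write(f"{idx}\t{vals}\n")

    @classmethod
    def read(cls, source: TextIO, protein_id: str = "protein") -> "EmbeddingTable":
        vectors: dict[int, np.ndarray] = {}
        for line in source:
            parts = line.split()
            if not parts:
                continue
            vectors[int(parts[0])] = np.array([float(x) for x in parts[1:]])
        if not vectors:
            raise ProfunError("empty embedding table")
        return cls(protein_id=protein_id, vectors=vectors)


def alpha_pq(d_tx: int, p: float, q: float) -> float:
    """Search-bias factor as a function of the previous-node distance."""
    if d_tx == 0:
        return 1.0 / p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / q
    raise ValueError(f"d_tx must be 0, 1 or 2; got {d_tx}")


class _WalkGraph:
    """Adjacency tables of the walk graph (self-loops stripped)."""

    def __init__(self, graph: ContactGraph):
        self.n = graph.n_nodes
        self.adj = np.zeros((self.n, self.n), dtype=bool)
        self.weights = np.zeros((self.n, self.n))
        for i, j in graph.edges:
            if i == j:
                continue
            w = graph.edge_weights.get((i, j), 1.0)
            self.adj[i, j] = self.adj[j, i] = True
            self.weights[i, j] = self.weights[j, i] = w
        self.neighbors = [np.flatnonzero(self.adj[v]) for v in range(self.n)]


def _step_probs(wg: _WalkGraph, prev: int | None, curr: int, p: float, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour array of ``curr`` and the transition probabilities over it."""
    nbrs = wg.neighbors[curr]
    if nbrs.size == 0:
        raise StrandedWalkerError(f"stranded walker at node {curr}")
    w = wg.weights[curr, nbrs]
    if prev is None:
        un = w.astype(float)
    else:
        alpha = np.where(
            nbrs == prev, 1.0 / p, np.where(wg.adj[prev, nbrs], 1.0, 1.0 / q)
        )
        un = alpha * w
    return nbrs, un / un.sum()


def transition_distribution(
    graph: ContactGraph,
    prev: int | None,
    curr: int,
    config: WalkConfig,
) -> dict[int, float]:
    """Exact next-step distribution over the neighbours of ``curr``.

    ``prev=None`` denotes the first step of a walk, which samples neighbours
    proportionally to edge weight.
    """
    wg = _WalkGraph(graph)
    if prev is not None and not wg.adj[prev, curr]:
        raise ValueError(f"prev={prev} is not adjacent to curr={curr}")
    nbrs, probs = _step_probs(wg, prev, curr, config.p, config.q)
    return {int(x): float(pr) for x, pr in zip(nbrs, probs)}


def generate_walks(graph: ContactGraph, config: WalkConfig) -> list[list[int]]:
    """Sample ``walks_per_node`` biased walks of ``walk_length`` from each node.

    Deterministic for a fixed ``config.seed``. A walker stranded on an
    isolated node yields a truncated walk rather than raising.
    """
    wg = _WalkGraph(graph)
    rng = np.random.default_rng(config.seed)
    walks: list[list[int]] = []
    for _ in range(config.walks_per_node):
        for start in range(wg.n):
            walk = [start]
            prev: int | None = None
            while len(walk) < config.walk_length:
                curr = walk[-1]
                try:
                    nbrs, probs = _step_probs(wg, prev, curr, config.p, config.q)
                except StrandedWalkerError:
                    break
                nxt = int(rng.choice(nbrs, p=probs))
                walk.append(nxt)
                prev = curr
            walks.append(walk)
    return walks


def _skipgram_pairs(
    walks: Sequence[Sequence[int]], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Center/context index pairs with word2vec-style random window shrink."""
    centers: list[int] = []
    contexts: list[int] = []
    for walk in walks:
        L = len(walk)
        spans = rng.integers(1, window + 1, size=L)
        for pos in range(L):
            b = int(spans[pos])
            for off in range(max(0, pos - b), min(L, pos + b + 1)):
                if off == pos:
                    continue
                centers.append(walk[pos])
                contexts.append(walk[off])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_embeddings(
    walks: Sequence[Sequence[int]],
    config: WalkConfig,
    protein_id: str = "protein",
    n_nodes: int | None = None,
) -> EmbeddingTable:
    """Skip-gram with negative sampling over the walk corpus.

    Maximises sum over (center, context) pairs of
    ``log sigma(u_ctx . v_cen) + sum_neg log sigma(-u_neg . v_cen)`` by
    vectorised SGD with a linearly decayed learning rate. Negatives are drawn
    from the unigram distribution raised to 3/4. Deterministic in
    ``config.seed``.

    Nodes absent from every walk receive a zero vector with a warning.
    """
    if not walks:
        raise ValueError("walks must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    dim = config.embedding_dim

    flat = np.concatenate([np.asarray(w, dtype=np.int64) for w in walks])
    if n_nodes is None:
        n_nodes = int(flat.max()) + 1
    counts = np.bincount(flat, minlength=n_nodes).astype(float)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        warnings.warn(
            f"{protein_id}: nodes {missing.tolist()} absent from all walks; "
            "they receive zero vectors",
            stacklevel=2,
        )
    noise = counts**0.75
    noise_sum = noise.sum()
    if noise_sum == 0:
        raise ValueError("no nodes appear in the walks")
    noise /= noise_sum

    vin = (rng.random((n_nodes, dim)) - 0.5) / dim  # input (center) vectors
    vout = np.zeros((n_nodes, dim))  # output (context) vectors

    centers, contexts = _skipgram_pairs(walks, config.context_window, rng)
    n_pairs = len(centers)
    batch = 256  # small enough that per-node update multiplicity stays sane
    total_steps = config.epochs * max(1, -(-n_pairs // batch))
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            lr = config.learning_rate * max(
                1e-4, 1.0 - step / max(1, total_steps)
            )
            step += 1
            sel = order[lo : lo + batch]
            cen, ctx = centers[sel], contexts[sel]
            neg = rng.choice(
                n_nodes, size=(len(sel), config.negative_samples), p=noise
            )
            vc = vin[cen]  # (B, d)
            uo = vout[ctx]  # (B, d)
            un = vout[neg]  # (B, K, d)

            pos_logit = np.clip(np.sum(vc * uo, axis=1), -30, 30)
            neg_logit = np.clip(np.einsum("bd,bkd->bk", vc, un), -30, 30)
            pos_score = 1.0 / (1.0 + np.exp(-pos_logit))  # (B,)
            neg_score = 1.0 / (1.0 + np.exp(-neg_logit))

            g_pos = (pos_score - 1.0)[:, None]  # d/d(vc.uo)
            g_neg = neg_score[..., None]  # (B, K, 1)

            grad_vc = g_pos * uo + np.sum(g_neg * un, axis=1)
            np.add.at(vin, cen, -lr * grad_vc)
            np.add.at(vout, ctx, -lr * (g_pos * vc))
            np.add.at(
                vout.reshape(-1, dim),
                neg.ravel(),
                -lr * (g_neg * vc[:, None, :]).reshape(-1, dim),
            )

    vin[missing] = 0.0
    vectors = {i: vin[i].copy() for i in range(n_nodes)}
    return EmbeddingTable(protein_id=protein_id, vectors=vectors)


def embed_protein(graph: ContactGraph, config: WalkConfig) -> EmbeddingTable:
    """Generate walks for ``graph`` and train embeddings on them.

    Degenerate graphs whose nodes have no non-self neighbours fall back to
    zero vectors for the stranded nodes.
    """
    walks = generate_walks(graph, config)
    return train_embeddings(
        walks, config, protein_id=graph.protein_id, n_nodes=graph.n_nodes
    )
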