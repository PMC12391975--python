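"""Dataset splitting, the training loop, and protein-centric metrics.

Fmax scans a threshold grid: at each threshold τ, precision is averaged over
the m(τ) proteins predicting at least one label with score ≥ τ, recall is
averaged over all n proteins (those with at least one true label), and Fmax
is the maximum harmonic mean over the grid. AUC and AUPR are micro-averaged
over all protein–term pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import ConfigError
from .model import GraphBatch, Model, ModelConfig, bce_loss

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "PredictionMatrix",
    "ProteinDataset",
    "split_dataset",
    "train",
    "fmax",
    "auc_score",
    "aupr_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.7
    valid_frac: float = 0.2
    test_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.valid_frac, self.test_frac)
        if any(f <= 0 for f in fracs):
            raise ConfigError("split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 30
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "epochs", "learning_rate", "early_stop_patience"):
            if getattr(self, name) < 0 or (name != "epochs" and getattr(self, name) == 0):
                raise ConfigError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ConfigError("weight_decay must be non-negative")


@dataclass
class PredictionMatrix:
    protein_ids: list[str]
    term_vocab: list[str]
    scores: np.ndarray  # (proteins, terms) in [0, 1]

    def __post_init__(self) -> None:
        assert self.scores.shape == (len(self.protein_ids), len(self.term_vocab))
        if self.scores.size and (
            self.scores.min() < 0 or self.scores.max() > 1
        ):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class ProteinDataset:
    """Aligned per-protein inputs and labels for training and evaluation."""

    protein_ids: list[str]
    adjacencies: list[np.ndarray]
    node_features: list[np.ndarray]
    seq_embeddings: np.ndarray  # (n, seq_dim)
    labels: np.ndarray  # (n, n_labels) binary
    term_vocab: list[str] = field(default_factory=list)

    def subset(self, ids: Sequence[str]) -> "ProteinDataset":
        index = {pid: i for i, pid in enumerate(self.protein_ids)}
        rows = [index[pid] for pid in ids]
        return ProteinDataset(
            protein_ids=list(ids),
            adjacencies=[self.adjacencies[i] for i in rows],
            node_features=[self.node_features[i] for i in rows],
            seq_embeddings=self.seq_embeddings[rows],
            labels=self.labels[rows],
            term_vocab=self.term_vocab,
        )

    def batch(self, rows: Sequence[int]) -> tuple[GraphBatch, np.ndarray, np.ndarray]:
        gb = GraphBatch(
            protein_ids=[self.protein_ids[i] for i in rows],
            adjacencies=[self.adjacencies[i] for i in rows],
            features=[self.node_features[i] for i in rows],
        )
        return gb, self.seq_embeddings[list(rows)], self.labels[list(rows)]

    def __len__(self) -> int:
        return len(self.protein_ids)


def split_dataset(
    protein_ids: Sequence[str], spec: SplitSpec
) -> tuple[list[str], list[str], list[str]]:
    """Random disjoint, exhaustive split with largest-remainder rounding."""
    ids = list(protein_ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 proteins to split")
    n = len(ids)
    fracs = np.array([spec.train_frac, spec.valid_frac, spec.test_frac])
    exact = fracs * n
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    for k in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[k] += 1
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


# ---------------------------------------------------------------------------
# metrics


def fmax(
    labels: np.ndarray,
    scores: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> tuple[float, float]:
    """Protein-centric Fmax over a threshold grid.

    Returns ``(fmax_value, best_threshold)``; ties resolve to the lowest
    threshold. Proteins without any true label are excluded from recall
    averaging (with a warning).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must share a shape")
    if thresholds is None:
        thresholds = np.round(np.linspace(0.0, 1.0, 101), 2)

    has_true = labels.sum(axis=1) > 0
    if not has_true.all():
        warnings.warn(
            f"{int((~has_true).sum())} proteins with no true labels excluded "
            "from recall averaging",
            stacklevel=2,
        )
    labels = labels[has_true]
    scores = scores[has_true]
    n = labels.shape[0]
    if n == 0:
        raise ValueError("no proteins with true labels")

    best_f, best_tau = 0.0, 0.0
    for tau in thresholds:
        pred = scores >= tau
        pred_counts = pred.sum(axis=1)
        covered = pred_counts > 0
        m = int(covered.sum())
        if m == 0:
            continue
        tp = (pred & (labels > 0)).sum(axis=1)
        pr = float((tp[covered] / pred_counts[covered]).mean())
        rc = float((tp / labels.sum(axis=1)).mean())  # mean over all n
        if pr + rc == 0:
            continue
        f = 2 * pr * rc / (pr + rc)
        if f > best_f + 1e-15:
            best_f, best_tau = f, float(tau)
    return best_f, best_tau


def _pairwise_metric(labels, scores, average: str, metric) -> float:
    y = np.asarray(labels)
    s = np.asarray(scores)
    if average == "micro":
        y, s = y.ravel(), s.ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("metric undefined: labels contain a single class")
        return float(metric(y, s))
    if average == "macro":
        vals = [
            metric(y[:, j], s[:, j])
            for j in range(y.shape[1])
            if len(np.unique(y[:, j])) == 2
        ]
        if not vals:
            raise ValueError("metric undefined: no two-class term column")
        return float(np.mean(vals))
    raise ValueError("average must be 'micro' or 'macro'")


def auc_score(labels: np.ndarray, scores: np.ndarray, average: str = "micro") -> float:
    """ROC AUC over protein–term pairs (micro) or averaged by term (macro)."""
    return _pairwise_metric(labels, scores, average, roc_auc_score)


def aupr_score(labels: np.ndarray, scores: np.ndarray, average: str = "micro") -> float:
    """Area under the precision-recall curve (step method)."""
    return _pairwise_metric(labels, scores, average, average_precision_score)


def namespace_defaults(namespace: str) -> TrainConfig:
    """Per-namespace tuning defaults: dropout/batch 0.2/32 for MFO and CCO,
    0.3/64 for BPO."""
    if namespace in ("MFO", "CCO"):
        return TrainConfig(batch_size=32)
    if namespace == "BPO":
        return TrainConfig(batch_size=64)
    raise ValueError(f"unknown namespace {namespace!r}")


def namespace_dropout(namespace: str) -> float:
    return {"MFO": 0.2, "CCO": 0.2, "BPO": 0.3}[namespace]


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    """Adaptive-moment SGD with global gradient-norm clipping."""

    def __init__(
        self,
        model: Model,
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float = 1.0,
        weight_decay: float = 0.0,
    ):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in model.params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in model.params.items()}

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(
                    float((t.grad**2).sum())
                    for t in self.model.params.values()
                    if t.grad is not None
                )
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for t in self.model.params.values():
                    if t.grad is not None:
                        t.grad = t.grad * scale
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, tensor in self.model.params.items():
            g = tensor.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            tensor.data -= (
                self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            )
            if self.weight_decay:
                tensor.data -= self.lr * self.weight_decay * tensor.data


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    valid_fmax: float


def predict(model: Model, dataset: ProteinDataset, batch_size: int = 64) -> np.ndarray:
    """Eval-mode scores, (len(dataset), n_labels)."""
    out = []
    for lo in range(0, len(dataset), batch_size):
        rows = range(lo, min(lo + batch_size, len(dataset)))
        gb, seq, _ = dataset.batch(list(rows))
        out.append(model.forward(gb, seq, train=False).data)
    return np.vstack(out) if out else np.zeros((0, model.config.n_labels))


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_set: ProteinDataset,
    valid_set: ProteinDataset,
) -> tuple[Model, list[EpochLog]]:
    """Train with Adam on binary cross-entropy; keep the best-validation state.

    Returns the model loaded with the state of the epoch with highest
    validation Fmax, plus the per-epoch log. Deterministic for fixed seeds.
    Aborts on non-finite loss.
    """
    model = Model(model_config)
    opt = Adam(
        model,
        lr=train_config.learning_rate,
        weight_decay=train_config.weight_decay,
    )
    rng = np.random.default_rng(train_config.seed)
    log: list[EpochLog] = []
    best_state = model.state_dict()
    best_fmax = -1.0
    stale = 0

    for epoch in range(train_config.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for lo in range(0, len(order), train_config.batch_size):
            rows = order[lo : lo + train_config.batch_size].tolist()
            gb, seq, y = train_set.batch(rows)
            model.zero_grad()
            probs = model.forward(gb, seq, train=True)
            loss = bce_loss(probs, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_scores = predict(model, valid_set)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val_fmax, _ = fmax(valid_set.labels, val_scores)
        log.append(EpochLog(epoch, float(np.mean(losses)), val_fmax))
        logger.info(
            "epoch %d: loss %.4f, valid Fmax %.4f", epoch, log[-1].train_loss, val_fmax
        )
        if val_fmax > best_fmax:
            best_fmax, best_state, stale = val_fmax, model.state_dict(), 0
        else:
            stale += 1
            if stale >= train_config.early_stop_patience:
                break

    model.load_state(best_state)
    return model, log
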