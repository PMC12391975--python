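"""End-to-end pipeline with digest-based stage skipping.

Stages: simulate → build-graphs → embed-nodes → embed-seqs → prepare-labels
→ train → evaluate. Each stage records a digest of its inputs and
parameters under ``<out>/.digests.json``; a rerun skips stages whose inputs,
parameters and outputs are unchanged and recomputes everything downstream
of a change.

Configuration is a flat ``section.key = value`` text file overriding the
dataclass defaults of each component (sections: synth, graph, walk, seq,
labels, model, train, split).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError, ProfunError
from .golabels import (
    LabelMatrix,
    build_label_matrix,
    filter_rare_terms,
    parse_obo,
    propagate,
    read_annotations,
)
from .model import Model, ModelConfig
from .node2vec import EmbeddingTable, WalkConfig, embed_protein
from .sequence import (
    SequenceRecord,
    load_plm_embeddings,
    mock_embed,
    one_hot_encode,
    read_fasta,
    write_embeddings,
)
from .structure_graph import (
    build_contact_graph,
    parse_structure,
    read_edge_list,
    write_edge_list,
)
from .synth import SyntheticSpec, generate_dataset
from .train_eval import (
    ProteinDataset,
    SplitSpec,
    TrainConfig,
    aupr_score,
    auc_score,
    fmax,
    predict,
    split_dataset,
    train,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class GraphStageConfig:
    threshold_angstrom: float = 10.0
    add_self_loops: bool = True


@dataclass
class SeqStageConfig:
    mode: str = "mock"  # mock | onehot-mean | plm
    dim: int = 64
    seed: int = 0
    plm_file: str = ""


@dataclass
class LabelStageConfig:
    namespace: str = "MFO"
    min_proteins: int = 25


@dataclass
class ModelStageConfig:
    """ModelConfig fields whose values the pipeline does not infer."""

    n_blocks: int = 6
    hidden_dim: int = 32
    sag_ratio: float = 0.75
    transformer_layers: int = 3
    attention_heads: int = 8
    classifier_layers: int = 3
    dropout: float = 0.2
    use_onehot_node_features: bool = True
    readout_agg: str = "sum"
    seed: int = 0


def _desk_scale_walk() -> WalkConfig:
    # lighter than the WalkConfig defaults so a 200-protein pipeline run
    # finishes in minutes on one CPU
    return WalkConfig(
        walks_per_node=5, walk_length=20, context_window=5,
        epochs=3, embedding_dim=16,
    )


def _desk_scale_train() -> TrainConfig:
    return TrainConfig(epochs=60, learning_rate=3e-3, early_stop_patience=20)


@dataclass
class PipelineConfig:
    synth: SyntheticSpec = field(default_factory=SyntheticSpec)
    graph: GraphStageConfig = field(default_factory=GraphStageConfig)
    walk: WalkConfig = field(default_factory=_desk_scale_walk)
    seq: SeqStageConfig = field(default_factory=SeqStageConfig)
    labels: LabelStageConfig = field(default_factory=LabelStageConfig)
    model: ModelStageConfig = field(default_factory=ModelStageConfig)
    train: TrainConfig = field(default_factory=_desk_scale_train)
    split: SplitSpec = field(default_factory=SplitSpec)

    def reseed(self, seed: int) -> "PipelineConfig":
        """Propagate one global seed into every seeded section."""
        return PipelineConfig(
            synth=replace(self.synth, seed=seed),
            graph=self.graph,
            walk=replace(self.walk, seed=seed),
            seq=replace(self.seq, seed=seed),
            labels=self.labels,
            model=replace(self.model, seed=seed),
            train=replace(self.train, seed=seed),
            split=replace(self.split, seed=seed),
        )


def _coerce(value: str, like) -> object:
    if isinstance(like, bool):
        if value.lower() in ("true", "1", "yes"):
            return True
        if value.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"expected boolean, got {value!r}")
    if isinstance(like, int):
        return int(value)
    if isinstance(like, float):
        return float(value)
    if isinstance(like, tuple):
        parts = [p.strip() for p in value.split(",")]
        return tuple(type(like[0])(p) for p in parts) if like else tuple(parts)
    return value


def load_config(path: str | Path | None) -> PipelineConfig:
    """Parse ``section.key = value`` lines over the defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    overrides: dict[str, dict[str, str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line or "." not in line.split("=")[0]:
            raise ConfigError(f"{path}:{lineno}: expected 'section.key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        section, name = key.split(".", 1)
        overrides.setdefault(section, {})[name] = value
    for section, kv in overrides.items():
        if not hasattr(cfg, section):
            raise ConfigError(f"unknown config section {section!r}")
        current = getattr(cfg, section)
        fields = {f.name: getattr(current, f.name) for f in dataclasses.fields(current)}
        updates = {}
        for name, value in kv.items():
            if name not in fields:
                raise ConfigError(f"unknown key {section}.{name}")
            updates[name] = _coerce(value, fields[name])
        setattr(cfg, section, replace(current, **updates))
    return cfg


# ---------------------------------------------------------------------------
# digests


class _DigestStore:
    def __init__(self, out_dir: Path):
        self.path = out_dir / ".digests.json"
        self.data: dict[str, str] = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        return self.data.get(stage) == digest and all(p.exists() for p in outputs)

    def record(self, stage: str, digest: str) -> None:
        self.data[stage] = digest
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _digest(*parts: object) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, Path):
            if part.is_dir():
                for f in sorted(part.rglob("*")):
                    if f.is_file():
                        h.update(f.name.encode())
                        h.update(f.read_bytes())
            elif part.exists():
                h.update(part.read_bytes())
        else:
            h.update(repr(part).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, data_dir: Path) -> None:
    generate_dataset(cfg.synth, data_dir)


def stage_build_graphs(cfg: GraphStageConfig, pdb_dir: Path, graphs_dir: Path) -> None:
    graphs_dir.mkdir(parents=True, exist_ok=True)
    pdb_files = sorted(pdb_dir.glob("*.pdb"))
    if not pdb_files:
        raise ProfunError(f"no .pdb files under {pdb_dir}")
    for pdb_path in pdb_files:
        pid = pdb_path.stem
        chain = parse_structure(pdb_path.read_text(), protein_id=pid)
        graph = build_contact_graph(
            chain, cfg.threshold_angstrom, cfg.add_self_loops
        )
        with open(graphs_dir / f"{pid}.edges.tsv", "w") as fh:
            write_edge_list(graph, fh)
        (graphs_dir / f"{pid}.seq.txt").write_text(chain.sequence + "\n")


def stage_embed_nodes(cfg: WalkConfig, graphs_dir: Path, emb_dir: Path) -> None:
    emb_dir.mkdir(parents=True, exist_ok=True)
    for edge_path in sorted(graphs_dir.glob("*.edges.tsv")):
        pid = edge_path.stem.replace(".edges", "")
        with open(edge_path) as fh:
            graph = read_edge_list(fh, protein_id=pid)
        table = embed_protein(graph, cfg)
        with open(emb_dir / f"{pid}.emb.tsv", "w") as fh:
            table.write(fh)


def stage_embed_seqs(cfg: SeqStageConfig, fasta: Path, out_file: Path) -> None:
    from .sequence import onehot_mean_embed

    with open(fasta) as fh:
        records = read_fasta(fh)
    if cfg.mode == "mock":
        embs = [mock_embed(r, cfg.dim, cfg.seed) for r in records]
    elif cfg.mode == "onehot-mean":
        embs = [onehot_mean_embed(r) for r in records]
    elif cfg.mode == "plm":
        with open(cfg.plm_file) as fh:
            table = load_plm_embeddings(fh)
        missing = [r.protein_id for r in records if r.protein_id not in table]
        if missing:
            raise ProfunError(f"missing PLM embeddings for: {missing}")
        embs = [table[r.protein_id] for r in records]
    else:
        raise ConfigError(f"unknown seq embedding mode {cfg.mode!r}")
    with open(out_file, "w") as fh:
        write_embeddings(embs, fh)


def stage_prepare_labels(
    cfg: LabelStageConfig, obo: Path, annotations: Path, out_file: Path
) -> LabelMatrix:
    dag = parse_obo(obo.read_text())
    with open(annotations) as fh:
        ann = read_annotations(fh, cfg.namespace)
    ann = propagate(ann, dag)
    vocab = filter_rare_terms(ann, cfg.min_proteins, dag=dag)
    matrix = build_label_matrix(ann, vocab)
    with open(out_file, "w") as fh:
        matrix.write(fh)
    return matrix


def load_dataset(out_dir: Path, use_onehot: bool) -> ProteinDataset:
    """Assemble aligned graphs, node features, embeddings and labels."""
    with open(out_dir / "labels.tsv") as fh:
        labels = LabelMatrix.read(fh)
    seq_embs: dict[str, np.ndarray] = {}
    with open(out_dir / "seq_embeddings.tsv") as fh:
        for line in fh:
            parts = line.split("\t")
            seq_embs[parts[0]] = np.array([float(x) for x in parts[1:]])

    pids, adjs, feats, embs, rows = [], [], [], [], []
    for i, pid in enumerate(labels.protein_ids):
        edge_path = out_dir / "graphs" / f"{pid}.edges.tsv"
        emb_path = out_dir / "node_embeddings" / f"{pid}.emb.tsv"
        if not (edge_path.exists() and emb_path.exists() and pid in seq_embs):
            logger.warning("skipping %s: missing graph, embedding or sequence", pid)
            continue
        with open(edge_path) as fh:
            graph = read_edge_list(fh, protein_id=pid)
        with open(emb_path) as fh:
            table = EmbeddingTable.read(fh, protein_id=pid)
        X = table.as_matrix(graph.n_nodes)
        if use_onehot:
            seq = (out_dir / "graphs" / f"{pid}.seq.txt").read_text().strip()
            X = np.hstack([X, one_hot_encode(SequenceRecord(pid, seq))])
        pids.append(pid)
        adjs.append(graph.adjacency(self_loops=True))
        feats.append(X)
        embs.append(seq_embs[pid])
        rows.append(i)
    if not pids:
        raise ProfunError("no proteins with complete inputs")
    return ProteinDataset(
        protein_ids=pids,
        adjacencies=adjs,
        node_features=feats,
        seq_embeddings=np.vstack(embs),
        labels=labels.matrix[rows].astype(np.float64),
        term_vocab=labels.term_vocab,
    )


def _write_predictions(path: Path, ids, vocab, scores) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tterm_id\tscore\n")
        for pid, row in zip(ids, scores):
            for tid, s in zip(vocab, row):
                fh.write(f"{pid}\t{tid}\t{s:.6f}\n")


def stage_train_eval(
    cfg: PipelineConfig, out_dir: Path
) -> dict[str, float]:
    dataset = load_dataset(out_dir, cfg.model.use_onehot_node_features)
    train_ids, valid_ids, test_ids = split_dataset(dataset.protein_ids, cfg.split)
    (out_dir / "splits.json").write_text(
        json.dumps(
            {"train": train_ids, "valid": valid_ids, "test": test_ids}, indent=2
        )
    )
    node_dim = dataset.node_features[0].shape[1]
    model_config = ModelConfig(
        n_labels=dataset.labels.shape[1],
        node_feature_dim=node_dim - (21 if cfg.model.use_onehot_node_features else 0),
        seq_embedding_dim=dataset.seq_embeddings.shape[1],
        **{
            f.name: getattr(cfg.model, f.name)
            for f in dataclasses.fields(ModelStageConfig)
        },
    )
    model, log = train(
        model_config,
        cfg.train,
        dataset.subset(train_ids),
        dataset.subset(valid_ids),
    )
    model.save(str(out_dir / "model.npz"))
    with open(out_dir / "train_log.tsv", "w") as fh:
        fh.write("epoch\ttrain_loss\tvalid_fmax\n")
        for entry in log:
            fh.write(f"{entry.epoch}\t{entry.train_loss:.6f}\t{entry.valid_fmax:.6f}\n")

    test_set = dataset.subset(test_ids)
    scores = predict(model, test_set)
    _write_predictions(
        out_dir / "predictions.tsv", test_set.protein_ids, dataset.term_vocab, scores
    )
    f, tau = fmax(test_set.labels, scores)
    metrics = {
        "fmax": f,
        "fmax_threshold": tau,
        "auc": auc_score(test_set.labels, scores),
        "aupr": aupr_score(test_set.labels, scores),
    }
    with open(out_dir / "metrics.txt", "w") as fh:
        fh.write(f"# profun {__version__} metrics report\n")
        for key in sorted(metrics):
            fh.write(f"{key}\t{metrics[key]:.6f}\n")
    return metrics


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    data_dir: str | Path | None = None,
    simulate: bool = True,
) -> dict[str, float]:
    """Run every stage, skipping those whose digests are unchanged.

    ``data_dir`` defaults to ``<out>/data`` and is generated by the
    synthetic-data stage when ``simulate`` is true.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(data_dir) if data_dir is not None else out_dir / "data"
    store = _DigestStore(out_dir)

    if simulate:
        d = _digest(cfg.synth, __version__)
        if not store.fresh("simulate", d, [data_dir / "go.obo"]):
            logger.info("stage simulate: running")
            stage_simulate(cfg, data_dir)
            store.record("simulate", d)
        else:
            logger.info("stage simulate: up to date")

    graphs_dir = out_dir / "graphs"
    d = _digest(cfg.graph, data_dir / "pdb", __version__)
    if not store.fresh("build_graphs", d, [graphs_dir]):
        logger.info("stage build_graphs: running")
        stage_build_graphs(cfg.graph, data_dir / "pdb", graphs_dir)
        store.record("build_graphs", d)
    else:
        logger.info("stage build_graphs: up to date")

    emb_dir = out_dir / "node_embeddings"
    d = _digest(cfg.walk, graphs_dir, __version__)
    if not store.fresh("embed_nodes", d, [emb_dir]):
        logger.info("stage embed_nodes: running")
        stage_embed_nodes(cfg.walk, graphs_dir, emb_dir)
        store.record("embed_nodes", d)
    else:
        logger.info("stage embed_nodes: up to date")

    seq_file = out_dir / "seq_embeddings.tsv"
    d = _digest(cfg.seq, data_dir / "sequences.fasta", __version__)
    if not store.fresh("embed_seqs", d, [seq_file]):
        logger.info("stage embed_seqs: running")
        stage_embed_seqs(cfg.seq, data_dir / "sequences.fasta", seq_file)
        store.record("embed_seqs", d)
    else:
        logger.info("stage embed_seqs: up to date")

    labels_file = out_dir / "labels.tsv"
    d = _digest(cfg.labels, data_dir / "go.obo", data_dir / "annotations.tsv", __version__)
    if not store.fresh("prepare_labels", d, [labels_file]):
        logger.info("stage prepare_labels: running")
        stage_prepare_labels(
            cfg.labels, data_dir / "go.obo", data_dir / "annotations.tsv", labels_file
        )
        store.record("prepare_labels", d)
    else:
        logger.info("stage prepare_labels: up to date")

    metrics_file = out_dir / "metrics.txt"
    d = _digest(
        cfg.model, cfg.train, cfg.split,
        graphs_dir, emb_dir, seq_file, labels_file, __version__,
    )
    if not store.fresh("train_eval", d, [metrics_file]):
        logger.info("stage train_eval: running")
        metrics = stage_train_eval(cfg, out_dir)
        store.record("train_eval", d)
    else:
        logger.info("stage train_eval: up to date")
        metrics = {}
        for line in metrics_file.read_text().splitlines():
            if line.startswith("#"):
                continue
            key, value = line.split("\t")
            metrics[key] = float(value)
    return metrics
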