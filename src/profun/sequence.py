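"""Sequence features: one-hot residue matrices and global embeddings.

Global per-protein embeddings come from one of three sources: an external
protein-language-model file loaded verbatim (precomputed offline), a
deterministic k-mer hash mock used in tests and desk-scale runs, or the mean
of the one-hot matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np

from .errors import EmbeddingError

__all__ = [
    "ALPHABET",
    "SequenceRecord",
    "GlobalSequenceEmbedding",
    "one_hot_encode",
    "mean_pool",
    "load_plm_embeddings",
    "write_embeddings",
    "mock_embed",
    "read_fasta",
    "write_fasta",
]

# 20 canonical residues in one-letter alphabetical order, then 'X'
ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + "X"
_INDEX = {aa: k for k, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class SequenceRecord:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in _INDEX:
                raise ValueError(
                    f"{self.protein_id}: invalid residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GlobalSequenceEmbedding:
    protein_id: str
    vector: np.ndarray
    source: str = "plm"  # plm | mock | onehot-mean

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise EmbeddingError(f"{self.protein_id}: non-finite embedding")

    @property
    def dim(self) -> int:
        return len(self.vector)


def one_hot_encode(record: SequenceRecord) -> np.ndarray:
    """L × 21 binary matrix; row i marks the residue at position i."""
    out = np.zeros((len(record), len(ALPHABET)))
    for i, aa in enumerate(record.sequence):
        out[i, _INDEX[aa]] = 1.0
    return out


def mean_pool(per_position: np.ndarray) -> np.ndarray:
    """Column-wise arithmetic mean of an L × d matrix."""
    mat = np.asarray(per_position)
    if mat.ndim != 2 or mat.shape[0] == 0:
        raise ValueError("mean_pool expects a non-empty L x d matrix")
    return mat.mean(axis=0)


def load_plm_embeddings(source: TextIO) -> dict[str, GlobalSequenceEmbedding]:
    """Read tab-separated ``protein_id<TAB>v1<TAB>v2...`` embedding rows.

    All rows must share one dimensionality; produced offline by any external
    embedder.
    """
    table: dict[str, GlobalSequenceEmbedding] = {}
    dim: int | None = None
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise EmbeddingError(f"line {lineno}: expected id and vector")
        pid = parts[0]
        vec = np.array([float(x) for x in parts[1:]])
        if dim is None:
            dim = len(vec)
        elif len(vec) != dim:
            raise EmbeddingError(
                f"line {lineno}: inconsistent embedding dims "
                f"({len(vec)} vs {dim})"
            )
        table[pid] = GlobalSequenceEmbedding(pid, vec, source="plm")
    if not table:
        raise EmbeddingError("no embeddings in file")
    return table


def write_embeddings(
    embeddings: Iterable[GlobalSequenceEmbedding], sink: TextIO
) -> None:
    for emb in embeddings:
        vals = "\t".join(f"{v:.8g}" for v in emb.vector)
        sink.write(f"{emb.protein_id}\t{vals}\n")


def mock_embed(
    record: SequenceRecord, dim: int, seed: int, k: int = 3
) -> GlobalSequenceEmbedding:
    """Deterministic language-model stand-in from hashed k-mer counts.

    Each k-mer is hashed (with the seed) to a fixed random direction in R^dim
    and directions are summed weighted by k-mer frequency, so near-identical
    sequences land close in cosine similarity while unrelated sequences do
    not. Pure function of ``(sequence, dim, seed)``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    seq = record.sequence
    counts: dict[str, int] = {}
    if len(seq) < k:
        counts[seq] = 1
    else:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    vec = np.zeros(dim)
    total = sum(counts.values())
    for kmer, c in counts.items():
        digest = hashlib.sha256(f"{seed}:{kmer}".encode()).digest()
        sub_rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        vec += (c / total) * sub_rng.standard_normal(dim)
    return GlobalSequenceEmbedding(record.protein_id, vec, source="mock")


def onehot_mean_embed(record: SequenceRecord) -> GlobalSequenceEmbedding:
    """Composition-only 21-dim embedding: mean-pooled one-hot matrix."""
    return GlobalSequenceEmbedding(
        record.protein_id, mean_pool(one_hot_encode(record)), source="onehot-mean"
    )


def read_fasta(source: TextIO) -> list[SequenceRecord]:
    from Bio import SeqIO

    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(source, "fasta")
    ]
    if not records:
        raise ValueError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], sink: TextIO) -> None:
    for rec in records:
        sink.write(f">{rec.protein_id}\n{rec.sequence}\n")
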