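"""Gene Ontology parsing, annotation propagation and label matrices.

Only ``is_a`` edges are used. Annotations are closed upward under the
true-path rule, rare terms are dropped by a minimum-protein threshold, and
the surviving vocabulary becomes the columns of a binary label matrix.
Namespace roots are excluded from vocabularies (they would be annotated to
every protein after propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, TextIO

import networkx as nx
import numpy as np

from .errors import OboParseError

__all__ = [
    "GODag",
    "AnnotationSet",
    "LabelMatrix",
    "parse_obo",
    "propagate",
    "filter_rare_terms",
    "build_label_matrix",
    "read_annotations",
]

logger = logging.getLogger(__name__)

NAMESPACES = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
}


@dataclass(frozen=True)
class GOTerm:
    term_id: str
    name: str
    namespace: str  # MFO | BPO | CCO
    parents: frozenset[str]  # is_a parents


@dataclass
class GODag:
    """Acyclic ontology over ``is_a`` edges, obsolete terms excluded."""

    terms: dict[str, GOTerm]

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    raise OboParseError(
                        f"{term.term_id}: is_a parent {parent} not defined"
                    )
                if self.terms[parent].namespace != term.namespace:
                    raise OboParseError(
                        f"{term.term_id}: is_a crosses namespaces "
                        f"({term.namespace} -> {self.terms[parent].namespace})"
                    )
                g.add_edge(term.term_id, parent)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise OboParseError(f"cyclic is_a relationship: {cycle}")
        self._graph = g

    def ancestors(self, term_id: str) -> set[str]:
        """All is_a ancestors of ``term_id`` (excluding itself)."""
        return set(nx.descendants(self._graph, term_id))

    def roots(self, namespace: str | None = None) -> set[str]:
        out = {tid for tid, t in self.terms.items() if not t.parents}
        if namespace is not None:
            out = {tid for tid in out if self.terms[tid].namespace == namespace}
        return out

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


@dataclass
class AnnotationSet:
    """Protein → GO-term sets within one namespace."""

    records: dict[str, set[str]]
    namespace: str

    def validate(self, dag: GODag) -> None:
        for pid, terms in self.records.items():
            for tid in terms:
                if tid not in dag:
                    raise OboParseError(f"{pid}: unknown term {tid}")
                if dag.terms[tid].namespace != self.namespace:
                    raise OboParseError(
                        f"{pid}: term {tid} is {dag.terms[tid].namespace}, "
                        f"not {self.namespace}"
                    )


@dataclass
class LabelMatrix:
    protein_ids: list[str]
    term_vocab: list[str]
    matrix: np.ndarray  # binary, len(protein_ids) x len(term_vocab)

    def __post_init__(self) -> None:
        assert self.matrix.shape == (len(self.protein_ids), len(self.term_vocab))

    def write(self, sink: TextIO) -> None:
        sink.write("protein_id\t" + "\t".join(self.term_vocab) + "\n")
        for pid, row in zip(self.protein_ids, self.matrix):
            sink.write(pid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def read(cls, source: TextIO) -> "LabelMatrix":
        header = source.readline().rstrip("\n").split("\t")
        vocab = header[1:]
        pids: list[str] = []
        rows: list[list[int]] = []
        for line in source:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            pids.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
        return cls(pids, vocab, np.array(rows, dtype=np.int8))


def parse_obo(obo_text: str) -> GODag:
    """Parse OBO 1.2 ``[Term]`` stanzas into a DAG.

    Captures id, name, namespace and ``is_a`` lines; obsolete terms and all
    other relationship types are ignored.
    """
    terms: dict[str, GOTerm] = {}
    stanza: dict[str, list[str]] | None = None

    def flush(st: dict[str, list[str]] | None) -> None:
        if st is None or "id" not in st:
            return
        if st.get("is_obsolete", ["false"])[0].lower() == "true":
            return
        ns_raw = st.get("namespace", ["molecular_function"])[0]
        ns = NAMESPACES.get(ns_raw, ns_raw)
        if ns not in NAMESPACES.values():
            raise OboParseError(f"{st['id'][0]}: unknown namespace {ns_raw!r}")
        tid = st["id"][0]
        terms[tid] = GOTerm(
            term_id=tid,
            name=st.get("name", [""])[0],
            namespace=ns,
            parents=frozenset(st.get("is_a", [])),
        )

    in_term = False
    for raw in obo_text.splitlines():
        line = raw.split("!")[0].strip()
        if line == "[Term]":
            if in_term:
                flush(stanza)
            stanza, in_term = {}, True
            continue
        if line.startswith("["):  # [Typedef] etc.
            if in_term:
                flush(stanza)
            stanza, in_term = None, False
            continue
        if not in_term or not line or ":" not in line:
            continue
        key, value = line.split(":", 1)
        assert stanza is not None
        stanza.setdefault(key.strip(), []).append(value.strip())
    if in_term:
        flush(stanza)
    if not terms:
        raise OboParseError("no [Term] stanzas found")
    return GODag(terms)


def read_annotations(source: TextIO, namespace: str) -> AnnotationSet:
    """Read 2-column TSV ``protein_id<TAB>term_id`` annotation records."""
    records: dict[str, set[str]] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise OboParseError(
                f"line {lineno}: expected 'protein_id<TAB>term_id', got {line!r}"
            )
        records.setdefault(parts[0], set()).add(parts[1])
    return AnnotationSet(records=records, namespace=namespace)


def propagate(ann: AnnotationSet, dag: GODag) -> AnnotationSet:
    """Close every protein's term set upward under is_a (true-path rule).

    Terms outside ``ann.namespace`` are rejected by validation; the result is
    idempotent and never removes a term.
    """
    ann.validate(dag)
    out: dict[str, set[str]] = {}
    for pid, terms in ann.records.items():
        closed = set(terms)
        for tid in terms:
            closed |= dag.ancestors(tid)
        out[pid] = closed
    return AnnotationSet(records=out, namespace=ann.namespace)


def filter_rare_terms(
    ann: AnnotationSet,
    min_proteins: int = 25,
    dag: GODag | None = None,
) -> list[str]:
    """Vocabulary of terms annotated to at least ``min_proteins`` proteins.

    Sorted by term id. Namespace roots are excluded when ``dag`` is given.
    """
    counts: dict[str, int] = {}
    for terms in ann.records.values():
        for tid in terms:
            counts[tid] = counts.get(tid, 0) + 1
    roots = dag.roots(ann.namespace) if dag is not None else set()
    vocab = sorted(
        tid
        for tid, c in counts.items()
        if c >= min_proteins and tid not in roots
    )
    if not vocab:
        raise ValueError(
            f"no terms annotated to >= {min_proteins} proteins; "
            "lower --min-proteins"
        )
    return vocab


def build_label_matrix(ann: AnnotationSet, vocab: Iterable[str]) -> LabelMatrix:
    """Binary protein × term matrix over ``vocab``.

    Proteins with no in-vocabulary term are dropped (count logged).
    """
    vocab = list(vocab)
    col = {tid: j for j, tid in enumerate(vocab)}
    pids: list[str] = []
    rows: list[np.ndarray] = []
    dropped = 0
    for pid in sorted(ann.records):
        row = np.zeros(len(vocab), dtype=np.int8)
        for tid in ann.records[pid]:
            if tid in col:
                row[col[tid]] = 1
        if row.sum() == 0:
            dropped += 1
            continue
        pids.append(pid)
        rows.append(row)
    if dropped:
        logger.info("dropped %d proteins with no in-vocabulary terms", dropped)
    matrix = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(vocab)), dtype=np.int8)
    return LabelMatrix(protein_ids=pids, term_vocab=vocab, matrix=matrix)
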