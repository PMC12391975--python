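"""Residue chains and Cα contact graphs.

Parses single-chain PDB structures into ordered Cα traces and builds the
undirected residue contact graph: an edge joins residues whose Cα atoms lie
strictly closer than a distance threshold (default 10 Å), with optional
self-loops on every node for downstream spectral convolutions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import EdgeListParseError, StructureParseError

__all__ = [
    "ResidueChain",
    "ContactGraph",
    "parse_structure",
    "build_contact_graph",
    "write_edge_list",
    "read_edge_list",
]

# 3-letter -> 1-letter residue codes; anything else maps to 'X'
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueChain:
    """Ordered Cα trace of a single protein chain.

    Attributes
    ----------
    protein_id : str
        Identifier of the protein.
    residue_ids : list of int
        1-based residue sequence numbers, strictly increasing.
    sequence : str
        One-letter amino-acid codes, aligned with ``residue_ids``.
    ca_coords : (L, 3) ndarray
        Cα positions in Å.
    """

    protein_id: str
    residue_ids: tuple[int, ...]
    sequence: str
    ca_coords: np.ndarray

    def __post_init__(self) -> None:
        if len(self.residue_ids) == 0:
            raise StructureParseError(
                f"{self.protein_id}: chain must contain at least one residue"
            )
        if len(self.residue_ids) != len(self.sequence):
            raise StructureParseError(
                f"{self.protein_id}: residue ids and sequence length differ"
            )
        if self.ca_coords.shape != (len(self.residue_ids), 3):
            raise StructureParseError(
                f"{self.protein_id}: coordinate array shape "
                f"{self.ca_coords.shape} does not match chain length"
            )
        ids = np.asarray(self.residue_ids)
        if len(ids) > 1 and not np.all(np.diff(ids) > 0):
            raise StructureParseError(
                f"{self.protein_id}: residue numbers must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclass
class ContactGraph:
    """Undirected residue contact graph with optional self-loops.

    Edges are stored once per unordered pair ``(i, j)`` with ``i <= j``.
    ``edge_weights`` holds positive weights (default 1.0 throughout).
    """

    protein_id: str
    n_nodes: int
    edges: set[tuple[int, int]] = field(default_factory=set)
    has_self_loops: bool = True
    edge_weights: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(
                    f"{self.protein_id}: edge ({i},{j}) out of range "
                    f"[0,{self.n_nodes})"
                )
            if i > j:
                raise ValueError(
                    f"{self.protein_id}: edges must be stored as (min,max) pairs"
                )

    def weight(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        return self.edge_weights.get(key, 1.0)

    def neighbors(self, i: int, include_self: bool = False) -> list[int]:
        """Sorted neighbors of node ``i``; self-loops excluded unless asked."""
        out = set()
        for a, b in self.edges:
            if a == i and b == i:
                if include_self:
                    out.add(i)
            elif a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return sorted(out)

    def adjacency(self, self_loops: bool | None = None) -> np.ndarray:
        """Dense symmetric adjacency matrix.

        ``self_loops=None`` keeps the graph's own convention; True forces a
        unit diagonal (the Ã matrix), False strips the diagonal.
        """
        A = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            w = self.edge_weights.get((i, j), 1.0)
            A[i, j] = w
            A[j, i] = w
        if self_loops is True:
            np.fill_diagonal(A, np.maximum(np.diag(A), 1.0))
        elif self_loops is False:
            np.fill_diagonal(A, 0.0)
        return A

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactGraph):
            return NotImplemented
        return (
            self.n_nodes == other.n_nodes
            and self.edges == other.edges
            and self.has_self_loops == other.has_self_loops
        )


def parse_structure(pdb_text: str, protein_id: str = "protein") -> ResidueChain:
    """Extract the Cα trace of the first chain from PDB file content.

    Takes the first model, first chain and first alternate location. Residues
    without a Cα atom are dropped. Unknown residue names map to ``'X'``.

    Raises
    ------
    StructureParseError
        If no Cα atom is found or an ATOM record is malformed (the error
        message carries the offending line number).
    """
    _validate_atom_records(pdb_text, protein_id)
    import biotite.structure.io.pdb as bpdb

    try:
        pdb_file = bpdb.PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb_file.get_structure(model=1, altloc="first")
    except StructureParseError:
        raise
    except Exception as exc:  # biotite raises several internal types
        raise StructureParseError(f"{protein_id}: cannot parse PDB: {exc}") from exc

    ca = atoms[atoms.atom_name == "CA"]
    ca = ca[ca.element != "CA"]  # exclude calcium ions sharing the atom name
    if ca.array_length() == 0:
        raise StructureParseError(f"{protein_id}: no Cα atoms found")
    first_chain = ca.chain_id[0]
    ca = ca[ca.chain_id == first_chain]

    residue_ids: list[int] = []
    letters: list[str] = []
    coords: list[np.ndarray] = []
    seen: set[int] = set()
    for k in range(ca.array_length()):
        res_id = int(ca.res_id[k])
        if res_id in seen:  # duplicate Cα for one residue: keep the first
            continue
        seen.add(res_id)
        residue_ids.append(res_id)
        letters.append(THREE_TO_ONE.get(str(ca.res_name[k]).upper(), "X"))
        coords.append(ca.coord[k])

    order = np.argsort(residue_ids, kind="stable")
    return ResidueChain(
        protein_id=protein_id,
        residue_ids=tuple(int(residue_ids[k]) for k in order),
        sequence="".join(letters[k] for k in order),
        ca_coords=np.asarray([coords[k] for k in order], dtype=float),
    )


def _validate_atom_records(pdb_text: str, protein_id: str) -> None:
    """Reject ATOM records whose fixed coordinate columns are unreadable."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureParseError(
                f"{protein_id}: malformed ATOM record at line {lineno}: "
                f"record too short"
            )
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise StructureParseError(
                f"{protein_id}: malformed ATOM record at line {lineno}: "
                f"unreadable coordinates"
            ) from exc


def build_contact_graph(
    chain: ResidueChain,
    threshold_angstrom: float = 10.0,
    add_self_loops: bool = True,
) -> ContactGraph:
    """Contact graph: edge (i, j) iff ‖Cα_i − Cα_j‖ < threshold (strict).

    Node ``k`` is the ``k``-th residue of the chain (0-based, compacted over
    residues that carry a Cα atom). Self-loops are added on every node when
    ``add_self_loops`` is true.
    """
    if threshold_angstrom <= 0:
        raise ValueError("threshold_angstrom must be positive")
    n = len(chain)
    edges: set[tuple[int, int]] = set()
    if n > 1:
        dist = squareform(pdist(chain.ca_coords))
        ii, jj = np.nonzero(np.triu(dist < threshold_angstrom, k=1))
        edges = {(int(i), int(j)) for i, j in zip(ii, jj)}
    if add_self_loops:
        edges |= {(i, i) for i in range(n)}
    return ContactGraph(
        protein_id=chain.protein_id,
        n_nodes=n,
        edges=edges,
        has_self_loops=add_self_loops,
    )


def write_edge_list(graph: ContactGraph, sink: TextIO) -> None:
    """Write tab-separated 0-based node index pairs, one edge per line.

    A leading comment line records the node count so that isolated nodes
    survive the round trip.
    """
    sink.write(f"# nodes\t{graph.n_nodes}\n")
    for i, j in sorted(graph.edges):
        sink.write(f"{i}\t{j}\n")


def read_edge_list(source: TextIO, protein_id: str = "protein") -> ContactGraph:
    """Inverse of :func:`write_edge_list`; accepts any whitespace separation."""
    edges: set[tuple[int, int]] = set()
    n_nodes: int | None = None
    n_lines = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "nodes":
                try:
                    n_nodes = int(parts[1])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"line {lineno}: bad node count {parts[1]!r}"
                    ) from exc
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise EdgeListParseError(
                f"line {lineno}: expected two integers, got {line!r}"
            )
        try:
            i, j = int(tokens[0]), int(tokens[1])
        except ValueError as exc:
            raise EdgeListParseError(
                f"line {lineno}: non-integer token in {line!r}"
            ) from exc
        edges.add((min(i, j), max(i, j)))
        n_lines += 1
    if n_lines == 0 and n_nodes is None:
        raise EdgeListParseError("empty edge list")
    if n_nodes is None:
        n_nodes = max(max(i, j) for i, j in edges) + 1
    has_self_loops = all((i, i) in edges for i in range(n_nodes))
    return ContactGraph(
        protein_id=protein_id,
        n_nodes=n_nodes,
        edges=edges,
        has_self_loops=has_self_loops,
    )


def chain_to_fasta(chains: Iterable[ResidueChain], sink: TextIO) -> None:
    """Write the derived one-letter sequences as FASTA."""
    for chain in chains:
        sink.write(f">{chain.protein_id}\n{chain.sequence}\n")
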