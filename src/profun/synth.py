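"""Self-contained toy datasets: structures, sequences, ontology, annotations.

Generates ideal-geometry Cα traces (helix, extended strand, or self-avoiding
random coil), random sequences with planted motifs, a miniature is_a
ontology, and annotations in which labels are a learnable function of motif
presence and contact density — so the full pipeline is exercisable offline
with recoverable signal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence import ALPHABET, SequenceRecord, write_fasta
from .structure_graph import ResidueChain, build_contact_graph

__all__ = ["SyntheticSpec", "generate_chain", "chain_to_pdb", "generate_dataset"]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

FOLD_MODES = ("helix", "extended", "random-coil")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``motifs`` maps sequence motifs to term ids; ``contact_rules`` maps
    (low, high) mean-degree bands to term ids. Bands must not overlap.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (30, 80)
    n_terms: int = 12
    dag_depth: int = 3
    # single-letter runs: the generator guarantees the letters exist scattered
    # in every sequence, so a planted (clustered) motif changes residue
    # arrangement but not composition
    motifs: tuple[tuple[str, str], ...] = (
        ("WWWWWW", "GO:1000005"),
        ("CCCCCC", "GO:1000006"),
        ("MMMMMM", "GO:1000007"),
    )
    contact_rules: tuple[tuple[float, float, str], ...] = (
        (0.0, 4.0, "GO:1000008"),  # sparse contacts: extended / coil
        (4.0, 99.0, "GO:1000009"),  # dense contacts: helical
    )
    label_noise: float = 0.05
    motif_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        bands = sorted((lo, hi) for lo, hi, _ in self.contact_rules)
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if lo2 < hi1:
                raise ValueError("contact-rule bands overlap")
        valid = set(self.term_ids)
        used = {tid for _, tid in self.motifs} | {t for _, _, t in self.contact_rules}
        if not used <= valid:
            raise ValueError(f"rules reference unknown terms: {sorted(used - valid)}")

    @property
    def term_ids(self) -> list[str]:
        return [f"GO:{1000000 + k:07d}" for k in range(1, self.n_terms + 1)]


def generate_chain(
    length: int, fold_mode: str, seed: int, protein_id: str = "synth"
) -> tuple[ResidueChain, str]:
    """Ideal-geometry Cα trace plus its PDB serialisation.

    helix: 1.5 Å rise per residue, 100° turn, 2.3 Å radius. extended:
    collinear 3.8 Å spacing. random-coil: self-avoiding walk with 3.8 Å
    steps (minimum 4 Å between non-successive residues).
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if fold_mode not in FOLD_MODES:
        raise ValueError(f"fold_mode must be one of {FOLD_MODES}")
    rng = np.random.default_rng(seed)
    if fold_mode == "helix":
        t = np.arange(length)
        theta = np.deg2rad(100.0) * t
        coords = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t]
        )
    elif fold_mode == "extended":
        coords = np.column_stack(
            [3.8 * np.arange(length), np.zeros(length), np.zeros(length)]
        )
    else:  # self-avoiding random coil
        pts = [np.zeros(3)]
        while len(pts) < length:
            for _ in range(200):
                step = rng.standard_normal(3)
                step *= 3.8 / np.linalg.norm(step)
                cand = pts[-1] + step
                prior = np.asarray(pts[:-1]) if len(pts) > 1 else None
                if prior is None or np.linalg.norm(prior - cand, axis=1).min() >= 4.0:
                    pts.append(cand)
                    break
            else:  # stuck: restart the walk
                pts = [np.zeros(3)]
        coords = np.asarray(pts)

    seq = "".join(rng.choice(list(ALPHABET[:20]), size=length))
    chain = ResidueChain(
        protein_id=protein_id,
        residue_ids=tuple(range(1, length + 1)),
        sequence=seq,
        ca_coords=coords,
    )
    return chain, chain_to_pdb(chain)


def chain_to_pdb(chain: ResidueChain) -> str:
    """Serialise a Cα trace as fixed-column PDB ATOM records."""
    lines = []
    for k, (rid, aa) in enumerate(zip(chain.residue_ids, chain.sequence), start=1):
        x, y, z = chain.ca_coords[k - 1]
        res = _ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {k:5d}  CA  {res:<3s} A{rid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _with_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Plant ``motif`` at a random window, preserving composition if possible.

    Each needed letter is swapped in from elsewhere in the sequence, so the
    amino-acid composition is unchanged whenever the letters exist; only when
    a letter is absent is it substituted outright. This keeps motif labels
    invisible to composition-only features and detectable only positionally.
    """
    chars = list(seq)
    k = len(motif)
    pos = int(rng.integers(0, len(chars) - k + 1))
    window = set(range(pos, pos + k))
    for off, needed in enumerate(motif):
        i = pos + off
        if chars[i] == needed:
            continue
        donors = [
            j for j in range(len(chars))
            if j not in window and chars[j] == needed
        ]
        if donors:
            j = donors[int(rng.integers(0, len(donors)))]
            chars[i], chars[j] = chars[j], chars[i]
        else:
            chars[i] = needed
    return "".join(chars)


def _seed_motif_letters(
    seq: str,
    motifs: tuple[tuple[str, str], ...],
    rng: np.random.Generator,
) -> str:
    """Ensure every motif's letters occur scattered in ``seq``.

    Applied to every protein (labelled or not) so that letter counts carry no
    label information; a planted motif then only changes their arrangement.
    Positions already forming a run are broken up by the scatter choice only
    by chance, which is what the label-noise budget absorbs.
    """
    chars = list(seq)
    for motif, _ in motifs:
        for letter, needed in _letter_counts(motif).items():
            have = [i for i, c in enumerate(chars) if c == letter]
            deficit = needed - len(have)
            if deficit <= 0:
                continue
            candidates = [i for i, c in enumerate(chars) if c != letter]
            picks = rng.choice(len(candidates), size=deficit, replace=False)
            for k in picks:
                chars[candidates[int(k)]] = letter
    return "".join(chars)


def _letter_counts(motif: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in motif:
        out[c] = out.get(c, 0) + 1
    return out


def _build_obo(spec: SyntheticSpec) -> str:
    """Miniature single-namespace is_a DAG of ``dag_depth`` levels.

    Term 1 is the namespace root; intermediate levels take three terms each
    and every remaining term is a leaf on the deepest level, so the terms
    carrying planted signal stay leaves with uninformative ancestors.
    """
    terms = spec.term_ids
    depth = max(1, spec.dag_depth)
    levels: list[list[str]] = [[terms[0]]]
    rest = list(terms[1:])
    for d in range(1, depth):
        if d == depth - 1:
            levels.append(rest)
            rest = []
        else:
            take = min(3, max(0, len(rest) - 1))
            levels.append(rest[:take])
            rest = rest[take:]
    parent_of: dict[str, str] = {}
    for d in range(1, len(levels)):
        prev = levels[d - 1] if levels[d - 1] else [terms[0]]
        for k, tid in enumerate(levels[d]):
            parent_of[tid] = prev[k % len(prev)]
    out = io.StringIO()
    out.write("format-version: 1.2\nontology: synthetic\n\n")
    for tid in terms:
        out.write("[Term]\n")
        out.write(f"id: {tid}\n")
        out.write(f"name: synthetic term {tid[-2:]}\n")
        out.write("namespace: molecular_function\n")
        if tid in parent_of:
            out.write(f"is_a: {parent_of[tid]} ! parent\n")
        out.write("\n")
    return out.getvalue()


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write PDB files, FASTA, go.obo and annotations.tsv under ``out_dir``.

    Labels: each motif term is carried by proteins whose sequence contains
    the motif (motifs are planted in a ``motif_fraction`` subset); each
    contact-rule term by proteins whose contact-graph mean degree falls in
    the rule's band. Every label is then flipped independently with
    probability ``label_noise``. Byte-identical output for a fixed seed.
    """
    out_dir = Path(out_dir)
    (out_dir / "pdb").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range

    records: list[SequenceRecord] = []
    annotations: list[tuple[str, str]] = []
    all_terms = spec.term_ids
    rule_terms = {tid for _, _, tid in spec.contact_rules}
    motif_terms = {tid for _, tid in spec.motifs}

    for k in range(spec.n_proteins):
        pid = f"SYN{k:04d}"
        length = int(rng.integers(lo, hi + 1))
        fold = FOLD_MODES[int(rng.integers(0, len(FOLD_MODES)))]
        chain, pdb_text = generate_chain(
            length, fold, seed=int(rng.integers(0, 2**31)), protein_id=pid
        )
        seq = _seed_motif_letters(chain.sequence, spec.motifs, rng)
        for motif, _ in spec.motifs:
            if rng.random() < spec.motif_fraction:
                seq = _with_motif(seq, motif, rng)
        chain = ResidueChain(pid, chain.residue_ids, seq, chain.ca_coords)
        pdb_text = chain_to_pdb(chain)
        # motif labels reflect the final sequence (later plants may overwrite
        # earlier ones), so labels stay an exact function of the emitted data
        true_terms = {tid for motif, tid in spec.motifs if motif in seq}

        graph = build_contact_graph(chain, add_self_loops=False)
        mean_degree = 2.0 * len(graph.edges) / graph.n_nodes
        for lo_d, hi_d, tid in spec.contact_rules:
            if lo_d <= mean_degree < hi_d:
                true_terms.add(tid)

        # noise: independent label flips over the informative terms
        for tid in sorted(motif_terms | rule_terms):
            has = tid in true_terms
            if rng.random() < spec.label_noise:
                has = not has
            if has:
                annotations.append((pid, tid))

        (out_dir / "pdb" / f"{pid}.pdb").write_text(pdb_text)
        records.append(SequenceRecord(pid, seq))

    with open(out_dir / "sequences.fasta", "w") as fh:
        write_fasta(records, fh)
    (out_dir / "go.obo").write_text(_build_obo(spec))
    with open(out_dir / "annotations.tsv", "w") as fh:
        for pid, tid in annotations:
            fh.write(f"{pid}\t{tid}\n")
    return {
        "n_proteins": spec.n_proteins,
        "n_annotations": len(annotations),
        "terms": all_terms,
    }
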