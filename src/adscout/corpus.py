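"""Protein corpus handling: FASTA ingest, deduplication, identity clustering,
and slicing proteins into the fixed-length tile design space.

The tile — a 53-residue window advanced with a 10-residue stride — is the unit
of everything downstream: labeling, prediction, acquisition. Clustering is a
greedy longest-first representative selection in the CD-HIT style: a sequence
joins the first existing cluster whose representative it matches at or above
the identity threshold, otherwise it founds a new cluster. Identity is the
number of identical aligned positions in a global pairwise alignment divided
by the length of the shorter sequence. This is a test-scale stand-in for
CD-HIT, not a performance-engineered reimplementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical residues, alphabetical — the fixed channel order for all
#: encodings in this package.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)

DEFAULT_WINDOW = 53
DEFAULT_STRIDE = 10


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with provenance identifiers."""

    protein_id: str
    sequence: str
    genome_id: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")


@dataclass(frozen=True)
class Tile:
    """A fixed-length window of a parent protein (0-based, half-open)."""

    tile_id: str
    parent_id: str
    start: int
    sequence: str


def is_canonical(sequence: str) -> bool:
    return bool(sequence) and set(sequence) <= _CANONICAL_SET


def sanitize_records(records: list[ProteinRecord],
                     on_noncanonical: str = "skip") -> list[ProteinRecord]:
    """Uppercase sequences and handle non-canonical residues (X, U, B, Z, ...).

    ``on_noncanonical``: ``"skip"`` drops the whole protein (default — the
    assay can only encode canonical residues); ``"mask"`` maps every
    non-canonical residue to ``X`` so downstream encoders can emit a zero row.
    """
    if on_noncanonical not in ("skip", "mask"):
        raise ValueError(f"unknown non-canonical policy {on_noncanonical!r}")
    out = []
    for rec in records:
        seq = rec.sequence.upper()
        if set(seq) <= _CANONICAL_SET:
            out.append(ProteinRecord(rec.protein_id, seq, rec.genome_id))
        elif on_noncanonical == "mask":
            masked = "".join(c if c in _CANONICAL_SET else "X" for c in seq)
            out.append(ProteinRecord(rec.protein_id, masked, rec.genome_id))
        else:
            logger.info("skipping %s: non-canonical residues", rec.protein_id)
    return out


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[ProteinRecord]:
    """Read proteins from FASTA. Header convention: ``>protein_id genome_id=G``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genome_id = ""
        for token in rec.description.split()[1:]:
            if token.startswith("genome_id="):
                genome_id = token.split("=", 1)[1]
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), genome_id))
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    seqrecords = []
    for rec in records:
        desc = f"genome_id={rec.genome_id}" if rec.genome_id else ""
        seqrecords.append(
            SeqRecord(Seq(rec.sequence), id=rec.protein_id, description=desc))
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# Deduplication and greedy identity clustering


def deduplicate(records: list[ProteinRecord]
                ) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Collapse exact sequence duplicates, keeping the first occurrence.

    Returns the unique records (input order preserved) and a multiplicity map
    keyed by the kept record's id.
    """
    if not records:
        raise ValueError("no records to deduplicate")
    seen: dict[str, str] = {}
    unique: list[ProteinRecord] = []
    multiplicity: dict[str, int] = {}
    for rec in records:
        if rec.sequence in seen:
            multiplicity[seen[rec.sequence]] += 1
        else:
            seen[rec.sequence] = rec.protein_id
            unique.append(rec)
            multiplicity[rec.protein_id] = 1
    return unique, multiplicity


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None
                      ) -> float:
    """Identical aligned positions / length of the shorter sequence."""
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        matches += sum(a[i] == b[j] for i, j in zip(range(a0, a1), range(b0, b1)))
    return matches / min(len(a), len(b))


def cluster_representatives(records: list[ProteinRecord],
                            identity_threshold: float = 0.90
                            ) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy longest-first clustering at an identity threshold.

    Sequences are processed longest first (ties broken by id); each joins the
    first representative it matches at >= threshold, else founds a cluster.
    Returns representatives (in founding order) and an ``id -> representative
    id`` assignment covering every input.
    """
    if not records:
        raise ValueError("no records to cluster")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}")
    aligner = _make_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.protein_id))
    representatives: list[ProteinRecord] = []
    assignment: dict[str, str] = {}
    for rec in ordered:
        assigned = False
        for rep in representatives:
            if rec.sequence == rep.sequence or pairwise_identity(
                    rec.sequence, rep.sequence, aligner) >= identity_threshold:
                assignment[rec.protein_id] = rep.protein_id
                assigned = True
                break
        if not assigned:
            representatives.append(rec)
            assignment[rec.protein_id] = rec.protein_id
    return representatives, assignment


def deduplicate_and_represent(records: list[ProteinRecord],
                              identity_threshold: float = 0.90
                              ) -> tuple[list[ProteinRecord], dict[str, str],
                                         dict[str, int]]:
    """Exact dedup followed by greedy identity clustering.

    Returns (representatives, id -> representative id for every input record,
    multiplicity of each unique sequence).
    """
    unique, multiplicity = deduplicate(records)
    kept_by_id = {u.protein_id: u for u in unique}
    reps, assignment = cluster_representatives(unique, identity_threshold)
    # route records collapsed by exact dedup to their kept twin's cluster
    full_assignment: dict[str, str] = dict(assignment)
    seq_to_kept = {u.sequence: u.protein_id for u in unique}
    for rec in records:
        if rec.protein_id not in kept_by_id:
            full_assignment[rec.protein_id] = assignment[seq_to_kept[rec.sequence]]
    return reps, full_assignment, multiplicity


# ---------------------------------------------------------------------------
# Tiling


def slice_tiles(protein: ProteinRecord, window: int = DEFAULT_WINDOW,
                stride: int = DEFAULT_STRIDE) -> list[Tile]:
    """Slice a protein into fixed-length windows at a fixed stride.

    Tiles start at 0, stride, 2*stride, ... while ``start + window`` fits.
    Proteins shorter than the window yield no tiles; trailing residues not
    covered by a full window are dropped.
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    seq = protein.sequence
    tiles = []
    for start in range(0, len(seq) - window + 1, stride):
        tiles.append(Tile(
            tile_id=f"{protein.protein_id}|{start}",
            parent_id=protein.protein_id,
            start=start,
            sequence=seq[start:start + window],
        ))
    if not tiles:
        logger.debug("protein %s shorter than window (%d < %d): no tiles",
                     protein.protein_id, len(seq), window)
    return tiles


def tile_proteins(records: list[ProteinRecord], window: int = DEFAULT_WINDOW,
                  stride: int = DEFAULT_STRIDE) -> list[Tile]:
    return [t for rec in records for t in slice_tiles(rec, window, stride)]


def tiles_to_frame(tiles: list[Tile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.tile_id, t.parent_id, t.start, t.sequence) for t in tiles],
        columns=["tile_id", "parent_id", "start", "sequence"])


def frame_to_tiles(frame: pd.DataFrame) -> list[Tile]:
    return [Tile(r.tile_id, r.parent_id, int(r.start), r.sequence)
            for r in frame.itertuples(index=False)]


def write_tile_table(tiles: list[Tile], path) -> None:
    tiles_to_frame(tiles).to_csv(path, sep="\t", index=False)


def read_tile_table(path) -> list[Tile]:
    return frame_to_tiles(pd.read_csv(path, sep="\t"))
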