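"""Sequence containers, motif splitting, identity statistics and internal
tandem-repeat detection.

A symmetric repeat protein (here, a beta-propeller) decomposes into tandem
sequence motifs.  This module provides the containers for a parent sequence
partitioned into aligned motifs (:class:`MotifSet`), the pairwise-identity
metric underlying all "internal identity" statistics, and a self-alignment
repeat detector that recovers the motif periodicity of a protein without
prior knowledge of boundaries.

Coordinates are 0-based half-open internally; 1-based inclusive in all
serialised reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .substmodel import AMINO_ACIDS, AA_INDEX

__all__ = [
    "SequenceRecord", "MotifSet", "RepeatAnnotation", "BoundaryError",
    "pairwise_identity", "split_motifs", "detect_internal_repeats",
    "filter_by_internal_identity", "read_fasta", "write_fasta",
    "annotations_to_tsv",
]

_CANONICAL = set(AMINO_ACIDS)


class BoundaryError(ValueError):
    """Overlapping, unordered or out-of-range motif boundaries."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an identifier and free-text source tag.

    ``X`` (unknown residue) is tolerated on input when ``allow_x`` is set by
    the reader, but such records must be cleaned before entering any
    analysis; all analysis entry points reject non-canonical letters.
    """

    id: str
    residues: str
    source: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> "SequenceRecord":
        bad = set(self.residues) - _CANONICAL
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residues {sorted(bad)}")
        return self


# Global aligner used for the identity metric: Needleman-Wunsch with
# BLOSUM62, gap open 10 / extend 0.5.  The identity denominator counts only
# columns where neither sequence is gapped.
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_global_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _BLOSUM62
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


_GLOBAL_ALIGNER = _make_global_aligner()

# Integer-coded BLOSUM62 for fast ungapped scoring.
_B62 = np.zeros((20, 20))
for _i, _a in enumerate(AMINO_ACIDS):
    for _j, _b in enumerate(AMINO_ACIDS):
        _B62[_i, _j] = _BLOSUM62[_a, _b]


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int64,
                       count=len(seq))


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues between two sequences after global
    alignment, counting only columns where neither sequence is gapped.

    Symmetric; 1.0 for a sequence against itself.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    aln = _GLOBAL_ALIGNER.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    columns = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        seg_a, seg_b = a[sa:ea], b[sb:eb]
        columns += ea - sa
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
    if columns == 0:
        return 0.0
    return matches / columns


@dataclass
class MotifSet:
    """A parent sequence partitioned into aligned tandem motifs."""

    parent_id: str
    boundaries: list[tuple[int, int]]
    motifs: list[str]
    identity_matrix: np.ndarray = field(repr=False)
    avg_internal_identity: float = 0.0

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    def consensus(self) -> str:
        """Majority residue per position over equal-length motifs (ties by
        alphabetical order); motifs of unequal length are truncated to the
        shortest."""
        n = min(len(m) for m in self.motifs)
        cols = []
        for i in range(n):
            counts: dict[str, int] = {}
            for m in self.motifs:
                counts[m[i]] = counts.get(m[i], 0) + 1
            best = max(sorted(counts), key=lambda c: counts[c])
            cols.append(best)
        return "".join(cols)


def _identity_stats(motifs: list[str]) -> tuple[np.ndarray, float]:
    k = len(motifs)
    mat = np.eye(k)
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            ident = pairwise_identity(motifs[i], motifs[j])
            mat[i, j] = mat[j, i] = ident
            vals.append(ident)
    avg = float(np.mean(vals)) if vals else 1.0
    return mat, avg


def split_motifs(parent: SequenceRecord,
                 boundaries: list[tuple[int, int]]) -> MotifSet:
    """Partition ``parent`` into motifs at the given 0-based half-open
    boundaries and compute the pairwise identity matrix."""
    parent.validate()
    n = len(parent)
    prev_end = 0
    for start, end in boundaries:
        if not (0 <= start < end <= n):
            raise BoundaryError(
                f"{parent.id}: boundary [{start},{end}) outside [0,{n})")
        if start < prev_end:
            raise BoundaryError(
                f"{parent.id}: boundaries overlap or are unordered at "
                f"[{start},{end})")
        prev_end = end
    motifs = [parent.residues[s:e] for s, e in boundaries]
    mat, avg = _identity_stats(motifs)
    return MotifSet(parent_id=parent.id, boundaries=list(boundaries),
                    motifs=motifs, identity_matrix=mat,
                    avg_internal_identity=avg)


@dataclass
class RepeatAnnotation:
    """Result of internal-repeat detection on one protein."""

    parent_id: str
    n_motifs: int
    period: int
    motif_set: MotifSet | None = None
    score: float = 0.0

    def __post_init__(self):
        if self.n_motifs == 1 and self.motif_set is not None:
            raise ValueError("single-motif annotation must not carry motifs")

    @property
    def avg_internal_identity(self) -> float:
        return (self.motif_set.avg_internal_identity
                if self.motif_set is not None else float("nan"))


def _lag_score(coded: np.ndarray, p: int) -> float:
    """Summed BLOSUM62 self-alignment score on the diagonal at lag ``p``."""
    return float(_B62[coded[:-p], coded[p:]].sum())


def _ungapped_score(a: np.ndarray, b: np.ndarray) -> float:
    n = min(len(a), len(b))
    return float(_B62[a[:n], b[:n]].sum())


def detect_internal_repeats(parent: SequenceRecord, min_period: int = 20,
                            max_period: int = 60,
                            call_ratio: float = 0.25) -> RepeatAnnotation:
    """Detect tandem sequence repeats by scoring self-alignment diagonals.

    Every candidate period ``p`` in ``[min_period, max_period]`` (capped at
    half the sequence length) is scored by the summed BLOSUM62 score of the
    sequence against itself shifted by ``p``.  The best period is accepted
    as a multi-motif call only when the average motif-vs-consensus score
    reaches ``call_ratio`` times the consensus self-score; otherwise the
    protein is annotated as a single motif (n_motifs = 1).
    """
    parent.validate()
    coded = _encode(parent.residues)
    n = len(coded)
    hi = min(max_period, n // 2)
    if hi < min_period:
        return RepeatAnnotation(parent.id, 1, n)
    scores = {p: _lag_score(coded, p) for p in range(min_period, hi + 1)}
    best_p = max(scores, key=lambda p: (scores[p], -p))
    if scores[best_p] <= 0:
        return RepeatAnnotation(parent.id, 1, n)
    p = best_p
    k = int(round(n / p))
    if k < 2 or k * p > n * 1.1:
        return RepeatAnnotation(parent.id, 1, n)
    k = min(k, n // p)
    # anchor the motif frame: choose the start offset whose k consecutive
    # p-length windows agree best with their own consensus
    best = None
    for offset in range(0, n - k * p + 1):
        windows = [coded[offset + i * p: offset + (i + 1) * p]
                   for i in range(k)]
        cons = np.array([np.bincount(col, minlength=20).argmax()
                         for col in np.stack(windows).T])
        total = sum(_ungapped_score(w, cons) for w in windows)
        if best is None or total > best[0]:
            best = (total, offset, cons)
    total, offset, cons = best
    mean_motif_score = total / k
    cons_self = _ungapped_score(cons, cons)
    if mean_motif_score < call_ratio * cons_self:
        return RepeatAnnotation(parent.id, 1, n)
    boundaries = [(offset + i * p, offset + (i + 1) * p) for i in range(k)]
    motif_set = split_motifs(parent, boundaries)
    return RepeatAnnotation(parent.id, k, p, motif_set, scores[best_p])


def filter_by_internal_identity(
        annotations: list[RepeatAnnotation],
        threshold: float) -> list[RepeatAnnotation]:
    """Keep multi-motif annotations (>= 4 motifs) whose average internal
    identity reaches ``threshold`` (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [a for a in annotations
            if a.n_motifs >= 4 and a.motif_set is not None
            and a.motif_set.avg_internal_identity >= threshold]


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path | io.TextIOBase,
               source: str = "", allow_x: bool = False) -> list[SequenceRecord]:
    """Read protein FASTA into :class:`SequenceRecord` objects.

    Raises a ``ValueError`` naming the offending record for non-canonical
    residues unless ``allow_x`` permits ``X``.
    """
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        residues = str(rec.seq).upper()
        ok = _CANONICAL | ({"X"} if allow_x else set())
        bad = set(residues) - ok
        if bad:
            raise ValueError(
                f"record {rec.id}: non-canonical residues {sorted(bad)}")
        records.append(SequenceRecord(rec.id, residues, source))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path: str | Path) -> None:
    """Write (id, sequence) pairs or SequenceRecords as 60-column FASTA."""
    bio = []
    for rec in records:
        if isinstance(rec, SequenceRecord):
            rid, seq = rec.id, rec.residues
        else:
            rid, seq = rec
        bio.append(_BioSeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def annotations_to_tsv(annotations: list[RepeatAnnotation],
                       path: str | Path | None = None) -> pd.DataFrame:
    """Serialise annotations to TSV (1-based inclusive boundaries,
    semicolon-joined)."""
    rows = []
    for a in annotations:
        if a.motif_set is not None:
            bounds = ";".join(f"{s + 1}-{e}" for s, e in a.motif_set.boundaries)
            ident = round(a.motif_set.avg_internal_identity, 4)
        else:
            bounds, ident = "", ""
        rows.append({"parent_id": a.parent_id, "n_motifs": a.n_motifs,
                     "period": a.period, "avg_internal_identity": ident,
                     "boundaries": bounds})
    df = pd.DataFrame(rows, columns=["parent_id", "n_motifs", "period",
                                     "avg_internal_identity", "boundaries"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
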