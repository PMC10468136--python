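"""Pairwise alignment, redundancy reduction and the sequence-similarity network.

PAS domains are short (~100-120 aa) and extremely diverged, so family
structure is recovered from a similarity network: nodes are domain
sequences, edges are local-alignment hits that pass a significance and a
query-coverage filter.  At desk scale the all-vs-all search is done with
exact Smith-Waterman (affine gaps, BLOSUM62 by default) rather than a
seeded heuristic; the filters keep the roles of the database-scale search
(E < 0.05, query coverage > 80%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted in input sequences; X is an unknown residue and scores 0.
ALPHABET = frozenset(AMINO_ACIDS + "X")

# Karlin-Altschul parameters for gapped BLOSUM62 searches with gap costs
# 11 (existence) + 1 per residue, as used by protein BLAST.
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


class SequenceError(ValueError):
    """Raised for malformed sequences (bad characters, empty, duplicates)."""


@dataclass(frozen=True)
class DomainSequence:
    """One sensor-domain amino-acid sequence.

    Parameters
    ----------
    id:
        Unique identifier within a dataset.
    residues:
        Uppercase amino-acid string over the 20-letter alphabet; ``X``
        is allowed and scores zero against everything.
    taxonomy:
        Ordered lineage labels (kingdom -> species), possibly empty.
    family_hint:
        Ground-truth family label, carried only by synthetic data for
        recovery tests; never consulted by the analysis itself.
    """

    id: str
    residues: str
    taxonomy: tuple[str, ...] = ()
    family_hint: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)!r}; "
                "residues must be uppercase amino acids (X allowed)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one pairwise local (or global) alignment.

    ``identity`` is matches / alignment columns (gap columns included);
    ``short_identity`` is matches / min(sequence lengths), the convention
    of greedy redundancy-reduction tools.  Ranges are 0-based half-open.
    """

    score: float
    n_matches: int
    n_columns: int
    query_length: int
    subject_length: int
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    aligned_pairs: tuple[tuple[int, int], ...]
    n_gap_openings: int = 0

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0

    @property
    def short_identity(self) -> float:
        return self.n_matches / min(self.query_length, self.subject_length)

    @property
    def query_coverage(self) -> float:
        start, end = self.query_range
        return (end - start) / self.query_length

    @property
    def subject_coverage(self) -> float:
        start, end = self.subject_range
        return (end - start) / self.subject_length

    @property
    def n_mismatches(self) -> int:
        return len(self.aligned_pairs) - self.n_matches

    @property
    def n_gap_columns(self) -> int:
        return self.n_columns - len(self.aligned_pairs)


EMPTY_ALIGNMENT_KWARGS = dict(
    score=0.0, n_matches=0, n_columns=0,
    query_range=(0, 0), subject_range=(0, 0), aligned_pairs=(),
)


@lru_cache(maxsize=8)
def _matrix_with_x(name: str):
    """Load a substitution matrix and zero the X row/column."""
    try:
        mat = substitution_matrices.load(name)
    except FileNotFoundError as exc:  # pragma: no cover - depends on name set
        raise ValueError(f"unknown substitution matrix {name!r}") from exc
    mat = mat.copy()
    if "X" in mat.alphabet:
        i = mat.alphabet.index("X")
        mat[i, :] = 0.0
        mat[:, i] = 0.0
    return mat


@lru_cache(maxsize=16)
def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _matrix_with_x(matrix)
    # BLAST convention: a gap of length L costs gap_open + L * gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def _result_from_alignment(aln, qlen: int, slen: int) -> AlignmentResult:
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return AlignmentResult(query_length=qlen, subject_length=slen,
                               **EMPTY_ALIGNMENT_KWARGS)
    query = aln.target
    subject = aln.query
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for qi, si in zip(range(qs, qe), range(ss, se)):
            pairs.append((qi, si))
            if query[qi] == subject[si]:
                matches += 1
    gap_cols = 0
    openings = 0
    for k in range(1, len(qblocks)):
        dq = qblocks[k][0] - qblocks[k - 1][1]
        ds = sblocks[k][0] - sblocks[k - 1][1]
        gap_cols += dq + ds
        openings += (dq > 0) + (ds > 0)
    return AlignmentResult(
        score=float(aln.score),
        n_matches=matches,
        n_columns=len(pairs) + gap_cols,
        query_length=qlen,
        subject_length=slen,
        query_range=(int(qblocks[0][0]), int(qblocks[-1][1])),
        subject_range=(int(sblocks[0][0]), int(sblocks[-1][1])),
        aligned_pairs=tuple(pairs),
        n_gap_openings=openings,
    )


def local_align(a: DomainSequence, b: DomainSequence,
                matrix: str = DEFAULT_MATRIX,
                gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of ``a`` (query) vs ``b``.

    Returns an empty alignment (score 0) when no positive-scoring local
    alignment exists.  Among co-optimal alignments the first in the
    aligner's deterministic enumeration order is reported; the score is
    unique.
    """
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    score = aligner.score(a.residues, b.residues)
    if score <= 0:
        return AlignmentResult(query_length=len(a), subject_length=len(b),
                               **EMPTY_ALIGNMENT_KWARGS)
    aln = aligner.align(a.residues, b.residues)[0]
    return _result_from_alignment(aln, len(a), len(b))


def local_score(a: DomainSequence, b: DomainSequence,
                matrix: str = DEFAULT_MATRIX,
                gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Smith-Waterman score only (no traceback); clipped at 0."""
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    return max(0.0, float(aligner.score(a.residues, b.residues)))


def global_align(a: DomainSequence, b: DomainSequence,
                 matrix: str = DEFAULT_MATRIX,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND):
    """Needleman-Wunsch global alignment; returns the pair of gapped strings."""
    aligner = _aligner(matrix, gap_open, gap_extend, "global")
    aln = aligner.align(a.residues, b.residues)[0]
    return str(aln[0]), str(aln[1])


def bit_score(raw_score: float) -> float:
    """Karlin-Altschul normalized bit score for a raw alignment score."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def e_value(raw_score: float, query_length: int, subject_length: int) -> float:
    """Per-pair Karlin-Altschul expect value (search space = m * n)."""
    return KA_K * query_length * subject_length * math.exp(-KA_LAMBDA * raw_score)


def raw_score_from_bits(bits: float) -> float:
    """Invert :func:`bit_score` (used when reading edge tables)."""
    return (bits * math.log(2.0) + math.log(KA_K)) / KA_LAMBDA


def min_bits_for_significance(query_length: int, subject_length: int,
                              significance: float) -> float:
    """Bit score at which the per-pair expect value equals ``significance``."""
    return math.log2(query_length * subject_length / significance)


@dataclass(frozen=True)
class EdgeRecord:
    """One similarity hit in BLAST tabular (outfmt 6) terms.

    Coordinates are stored 0-based half-open; the TSV writer converts to
    the file format's 1-based inclusive convention.
    """

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    evalue: float
    bitscore: float


class SimilarityGraph:
    """Undirected weighted sequence-similarity network.

    Edge keys are lexicographically sorted id pairs; weights are raw
    alignment scores and must be positive.  ``records`` optionally keeps
    the outfmt-6 style hit metadata for serialization.
    """

    def __init__(self) -> None:
        self.nodes: set[str] = set()
        self.edges: dict[tuple[str, str], float] = {}
        self.records: dict[tuple[str, str], EdgeRecord] = {}

    @staticmethod
    def edge_key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_node(self, node_id: str) -> None:
        self.nodes.add(node_id)

    def add_edge(self, a: str, b: str, weight: float,
                 record: Optional[EdgeRecord] = None) -> None:
        if a == b:
            raise ValueError(f"self-edge on {a!r} not allowed")
        if weight <= 0:
            raise ValueError(f"edge weight must be positive, got {weight}")
        key = self.edge_key(a, b)
        self.nodes.update(key)
        # keep the better hit when both directions were recorded
        if key not in self.edges or weight > self.edges[key]:
            self.edges[key] = float(weight)
            if record is not None:
                self.records[key] = record

    def has_edge(self, a: str, b: str) -> bool:
        return self.edge_key(a, b) in self.edges

    def weight(self, a: str, b: str) -> float:
        return self.edges[self.edge_key(a, b)]

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node_id: str) -> list[str]:
        out = []
        for (a, b) in self.edges:
            if a == node_id:
                out.append(b)
            elif b == node_id:
                out.append(a)
        return out

    def incident_weight(self, node_id: str, within: Optional[set[str]] = None) -> float:
        """Sum of weights of edges incident to ``node_id`` (optionally
        restricted to neighbours inside ``within``)."""
        total = 0.0
        for (a, b), w in self.edges.items():
            if a == node_id and (within is None or b in within):
                total += w
            elif b == node_id and (within is None or a in within):
                total += w
        return total

    def count_cross_edges(self, group_a: set[str], group_b: set[str]) -> int:
        n = 0
        for (a, b) in self.edges:
            if (a in group_a and b in group_b) or (a in group_b and b in group_a):
                n += 1
        return n


def reduce_redundancy(
    sequences: Sequence[DomainSequence],
    identity_threshold: float = 0.8,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[list[DomainSequence], dict[str, str]]:
    """Greedy incremental redundancy reduction (CD-HIT style).

    Sequences are visited longest first; each is compared against the
    accepted representatives and joins the first one whose local-alignment
    identity, measured as matches / min(sequence lengths), strictly
    exceeds ``identity_threshold``; otherwise it founds a new group.

    Returns the representatives (in acceptance order) and a membership
    map ``sequence id -> representative id``.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    representatives: list[DomainSequence] = []
    membership: dict[str, str] = {}
    for seq in sorted(sequences, key=lambda s: (-len(s), s.id)):
        assigned = None
        for rep in representatives:
            if seq.residues == rep.residues:
                assigned = rep.id
                break
            result = local_align(seq, rep, matrix, gap_open, gap_extend)
            if result.short_identity > identity_threshold:
                assigned = rep.id
                break
        if assigned is None:
            representatives.append(seq)
            assigned = seq.id
        membership[seq.id] = assigned
    return representatives, membership


def build_network(
    sequences: Sequence[DomainSequence],
    min_coverage: float = 0.8,
    significance: float = 0.05,
    min_bit_score: Optional[float] = None,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> SimilarityGraph:
    """All-vs-all local alignment filtered into a similarity network.

    An undirected edge joins two sequences when the alignment is
    significant (per-pair Karlin-Altschul bit score at least
    ``log2(m*n/significance)``, or at least ``min_bit_score`` when that is
    given) and the aligned span covers more than ``min_coverage`` of the
    query in at least one direction.  The edge weight is the raw
    Smith-Waterman score.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to build a network")
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate sequence ids in input")
    graph = SimilarityGraph()
    for s in sequences:
        graph.add_node(s.id)
    for i in range(len(sequences)):
        a = sequences[i]
        for j in range(i + 1, len(sequences)):
            b = sequences[j]
            score = local_score(a, b, matrix, gap_open, gap_extend)
            if score <= 0:
                continue
            bits = bit_score(score)
            if min_bit_score is not None:
                threshold = min_bit_score
            else:
                threshold = min_bits_for_significance(len(a), len(b), significance)
            if bits < threshold:
                continue
            result = local_align(a, b, matrix, gap_open, gap_extend)
            if result.query_coverage <= min_coverage and result.subject_coverage <= min_coverage:
                continue
            record = EdgeRecord(
                query_id=a.id,
                subject_id=b.id,
                pident=100.0 * result.identity,
                length=result.n_columns,
                mismatch=result.n_mismatches,
                gapopen=result.n_gap_openings,
                query_range=result.query_range,
                subject_range=result.subject_range,
                evalue=e_value(score, len(a), len(b)),
                bitscore=bits,
            )
            graph.add_edge(a.id, b.id, result.score, record)
    return graph
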