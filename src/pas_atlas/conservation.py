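"""Per-cluster representative selection, star alignment and conservation.

Each cluster is summarized by a representative (the network medoid), a
center-star multiple alignment of all members against it, and a
per-column conservation profile.  The representative's residues define
the canonical column numbering that the cofactor rules are anchored to:
the key-residue rules refer to positions on the domain scaffold, so
insertions relative to the representative are deliberately outside the
motif coordinate system.

Information content per column is log2(20) minus the Shannon entropy of
the residue frequencies (gaps excluded from the entropy; the gap fraction
is reported separately): 0 bits for a uniform column, ~4.32 bits for an
invariant one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .similarity import (AMINO_ACIDS, DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN,
                         DEFAULT_MATRIX, DomainSequence, SimilarityGraph,
                         global_align)

GAP = "-"
MAX_IC = math.log2(20.0)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class EmptyAlignmentError(ValueError):
    """Raised when trimming (or input validation) empties an alignment."""


@dataclass
class MultipleAlignment:
    """A gapped multiple alignment with a designated representative row.

    ``representative_columns`` maps representative residue index ->
    alignment column, so motif coordinates given on the representative
    can be looked up in the alignment.
    """

    rows: dict[str, str]
    representative: Optional[str] = None
    representative_columns: dict[int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyAlignmentError("alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if self.representative_columns is None:
            self.representative_columns = {}

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> list[str]:
        if not 0 <= j < self.n_columns:
            raise IndexError(f"column {j} outside [0, {self.n_columns})")
        return [s[j] for s in self.rows.values()]


def select_representative(members: Iterable[str], graph: SimilarityGraph) -> str:
    """The cluster medoid: the member with the largest summed weight of
    within-cluster edges (ties to the lexicographically smallest id).

    A desk-scale surrogate for "best hit against the cluster's own
    profile": the medoid is the sequence the rest of the cluster aligns
    to best.
    """
    members = set(members)
    if not members:
        raise ValueError("cluster has no members")
    return min(members, key=lambda m: (-graph.incident_weight(m, within=members), m))


def _parse_pairwise(gapped_ref: str, gapped_mem: str, ref_length: int,
                    ) -> tuple[list[str], list[str]]:
    """Split a global pairwise alignment into per-reference-position
    member characters and inter-position insertion strings."""
    at_ref = [GAP] * ref_length
    insertions = [""] * (ref_length + 1)
    p = 0
    for rc, mc in zip(gapped_ref, gapped_mem):
        if rc == GAP:
            insertions[p] += mc
        else:
            at_ref[p] = mc
            p += 1
    return at_ref, insertions


def center_star_align(members: Sequence[DomainSequence], representative: str,
                      matrix: str = DEFAULT_MATRIX,
                      gap_open: float = DEFAULT_GAP_OPEN,
                      gap_extend: float = DEFAULT_GAP_EXTEND) -> MultipleAlignment:
    """Center-star multiple alignment anchored on the representative.

    Every member is globally aligned to the representative; the pairwise
    gap patterns are merged into a common coordinate system ("once a gap,
    always a gap").  The representative's residues map injectively to
    columns, recorded in ``representative_columns``.
    """
    if not members:
        raise EmptyAlignmentError("no members to align")
    by_id = {s.id: s for s in members}
    if representative not in by_id:
        raise ValueError(f"representative {representative!r} is not a member")
    ref = by_id[representative]
    L = len(ref)
    parsed: dict[str, tuple[list[str], list[str]]] = {}
    for seq in members:
        if seq.id == representative:
            continue
        gr, gm = global_align(ref, seq, matrix, gap_open, gap_extend)
        parsed[seq.id] = _parse_pairwise(gr, gm, L)
    ins_len = [0] * (L + 1)
    for _, insertions in parsed.values():
        for p, block in enumerate(insertions):
            ins_len[p] = max(ins_len[p], len(block))

    def build(at_ref: list[str], insertions: list[str]) -> str:
        parts = []
        for p in range(L):
            parts.append(insertions[p].ljust(ins_len[p], GAP))
            parts.append(at_ref[p])
        parts.append(insertions[L].ljust(ins_len[L], GAP))
        return "".join(parts)

    rows = {ref.id: build(list(ref.residues), [""] * (L + 1))}
    for seq in members:
        if seq.id == representative:
            continue
        at_ref, insertions = parsed[seq.id]
        rows[seq.id] = build(at_ref, insertions)

    rep_columns = {}
    col = 0
    for p in range(L):
        col += ins_len[p]
        rep_columns[p] = col
        col += 1
    return MultipleAlignment(rows=rows, representative=ref.id,
                             representative_columns=rep_columns)


@dataclass
class ConservationProfile:
    """Per-column residue frequencies, gap fraction, information content.

    ``frequencies`` is (n_columns, 20) over the amino-acid alphabet in
    :data:`AMINO_ACIDS` order, computed over non-gap symbols only; rows
    of all-gap columns are zero.  ``information`` is in bits.
    """

    frequencies: np.ndarray
    gap_fraction: np.ndarray
    information: np.ndarray
    consensus: str
    n_rows: int

    @property
    def n_columns(self) -> int:
        return len(self.information)

    def to_frame(self) -> pd.DataFrame:
        modal = self.frequencies.max(axis=1, initial=0.0)
        return pd.DataFrame({
            "column": np.arange(self.n_columns),
            "consensus": list(self.consensus),
            "modal_frequency": modal,
            "information": self.information,
            "gap_fraction": self.gap_fraction,
        })


def conservation_profile(msa: MultipleAlignment) -> ConservationProfile:
    """Column-wise conservation statistics of a multiple alignment."""
    n_cols = msa.n_columns
    counts = np.zeros((n_cols, 20))
    gaps = np.zeros(n_cols)
    for row in msa.rows.values():
        for j, c in enumerate(row):
            if c == GAP:
                gaps[j] += 1
            else:
                k = _AA_INDEX.get(c)
                if k is not None:  # X contributes to neither count nor gap total
                    counts[j, k] += 1
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    nonzero = totals > 0
    freqs[nonzero] = counts[nonzero] / totals[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    information = np.where(nonzero, MAX_IC + plogp.sum(axis=1), 0.0)
    information = np.clip(information, 0.0, MAX_IC)
    consensus = "".join(
        AMINO_ACIDS[int(np.argmax(counts[j]))] if nonzero[j] else GAP
        for j in range(n_cols))
    return ConservationProfile(
        frequencies=freqs,
        gap_fraction=gaps / msa.n_rows,
        information=information,
        consensus=consensus,
        n_rows=msa.n_rows,
    )


def conserved_positions(profile: ConservationProfile,
                        min_dominant_freq: float = 0.5,
                        max_gap: float = 0.5) -> list[tuple[int, str, float]]:
    """Columns whose modal residue reaches ``min_dominant_freq`` among
    non-gap symbols and whose gap fraction is at most ``max_gap``.

    Returns (column, modal residue, modal frequency) triples.
    """
    if not 0 < min_dominant_freq <= 1 or not 0 < max_gap <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    out = []
    for j in range(profile.n_columns):
        if profile.gap_fraction[j] > max_gap:
            continue
        row = profile.frequencies[j]
        if not row.any():
            continue
        k = int(np.argmax(row))
        if row[k] >= min_dominant_freq:
            out.append((j, AMINO_ACIDS[k], float(row[k])))
    return out


def trim_alignment(msa: MultipleAlignment, max_col_gap: float = 0.9,
                   min_row_coverage: float = 0.8) -> MultipleAlignment:
    """Drop hyper-gapped columns, then poorly covered rows.

    Columns with gap fraction > ``max_col_gap`` are removed first; then
    rows whose non-gap fraction over the surviving columns is below
    ``min_row_coverage``.  Raises :class:`EmptyAlignmentError` when
    nothing survives.
    """
    if not 0 < max_col_gap <= 1 or not 0 < min_row_coverage <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    n_rows = msa.n_rows
    keep_cols = []
    for j in range(msa.n_columns):
        gaps = sum(1 for s in msa.rows.values() if s[j] == GAP)
        if gaps / n_rows <= max_col_gap:
            keep_cols.append(j)
    if not keep_cols:
        raise EmptyAlignmentError("all columns exceeded the gap threshold")
    new_rows = {}
    for rid, s in msa.rows.items():
        trimmed = "".join(s[j] for j in keep_cols)
        non_gap = sum(1 for c in trimmed if c != GAP)
        if non_gap / len(keep_cols) >= min_row_coverage:
            new_rows[rid] = trimmed
    if not new_rows:
        raise EmptyAlignmentError("all rows fell below the coverage threshold")
    col_remap = {old: new for new, old in enumerate(keep_cols)}
    rep = msa.representative if msa.representative in new_rows else None
    rep_cols = {p: col_remap[c] for p, c in msa.representative_columns.items()
                if c in col_remap} if rep else {}
    return MultipleAlignment(rows=new_rows, representative=rep,
                             representative_columns=rep_cols)


def sample_cluster(members: Sequence[str], fraction: float = 0.01,
                   seed: int = 0) -> list[str]:
    """Uniform sample without replacement of size max(1, round(f * n))."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    members = sorted(members)
    size = max(1, int(round(fraction * len(members))))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x53414D50]))
    picked = rng.choice(len(members), size=size, replace=False)
    return [members[i] for i in sorted(picked)]
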