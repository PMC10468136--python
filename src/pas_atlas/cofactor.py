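"""Key-residue cofactor rules and the specific / possible / unknown triage.

A handful of residues at fixed positions on the domain scaffold determine
which cofactor a sensor domain can hold: a heme-ligating histidine on the
Fα helix (FixL/DosP-like) or on Eα (Aer2-like); a tryptophan on Fα as the
primary FAD determinant (NifL/Aer/AerC/MmoS), with a supporting histidine
and asparagine; a cysteine that covalently bonds FMN in LOV domains, with
supporting arginine and asparagine; and the cysteine/tyrosine/glutamate
triad that holds p-coumaric acid in photoactive yellow protein.

Each cluster is triaged: *specific* when all primary residues of some
rule are conserved (>= min_prevalence of members) at columns mapped to
the stated structural elements; *possible* when the cluster shows
conserved residues inside the binding cavity that match no rule; and
*unknown* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .conservation import (ConservationProfile, MultipleAlignment,
                           conserved_positions)

#: The nine structural elements of the domain fold, N- to C-terminal.
ELEMENTS = ("Aβ", "Bβ", "Cα", "Dα", "Eα", "Fα", "Gβ", "Hβ", "Iβ")


class ElementMapError(ValueError):
    """Raised when a cluster has no usable structural-element annotation."""


@dataclass(frozen=True)
class ElementMap:
    """Structural-element annotation of representative columns.

    ``columns`` maps representative residue index -> element label;
    ``cavity_columns`` is the subset of annotated columns lining the
    binding cavity.  Derived from curated structures in real use; the
    synthetic generator emits the true map for its own scaffold.
    """

    columns: Mapping[int, str]
    cavity_columns: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        bad = {e for e in self.columns.values() if e not in ELEMENTS}
        if bad:
            raise ElementMapError(f"unknown structural elements {sorted(bad)!r}")
        stray = set(self.cavity_columns) - set(self.columns)
        if stray:
            raise ElementMapError(
                f"cavity columns {sorted(stray)} are not annotated with an element")

    def columns_for(self, element: str) -> list[int]:
        return sorted(c for c, e in self.columns.items() if e == element)


@dataclass(frozen=True)
class CofactorRule:
    """One cofactor's key-residue signature.

    All ``primary`` (element, residue) pairs must be conserved for a
    specific call; ``secondary`` pairs are supporting evidence used only
    to break ties between rules.
    """

    name: str
    cofactor: str
    primary: tuple[tuple[str, str], ...]
    secondary: tuple[tuple[str, str], ...] = ()
    min_prevalence: Optional[float] = None  # per-rule override
    exemplars: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.primary:
            raise ValueError(f"rule {self.name!r} has no primary residues")
        if self.min_prevalence is not None and not 0 < self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in (0, 1]")


def builtin_rules() -> list[CofactorRule]:
    """The five built-in cofactor signatures."""
    return [
        CofactorRule(
            name="heme-Fa", cofactor="heme",
            primary=(("Fα", "H"),),
            exemplars=("FixL", "DosP"),
        ),
        CofactorRule(
            name="heme-Ea", cofactor="heme",
            primary=(("Eα", "H"),),
            exemplars=("Aer2",),
        ),
        CofactorRule(
            name="FAD", cofactor="FAD",
            primary=(("Fα", "W"),),
            secondary=(("Eα", "H"), ("Hβ", "N")),
            exemplars=("NifL", "Aer", "AerC", "MmoS"),
        ),
        CofactorRule(
            name="FMN-LOV", cofactor="FMN",
            primary=(("Fα", "C"),),
            secondary=(("Eα", "R"), ("Hβ", "N")),
            exemplars=("phototropin LOV",),
        ),
        CofactorRule(
            name="PYP", cofactor="PYP",
            primary=(("Bβ", "Y"), ("Cα", "E"), ("Dα", "C")),
            exemplars=("PYP",),
        ),
    ]


@dataclass
class FunctionalCall:
    """Triage result for one cluster."""

    category: str  # "specific" | "possible" | "unknown"
    cofactor: Optional[str] = None
    rule_name: Optional[str] = None
    evidence: tuple[tuple[int, str, float], ...] = ()  # (column, residue, prevalence)
    n_sequences_with_motif: int = 0

    def __post_init__(self) -> None:
        if self.category not in ("specific", "possible", "unknown"):
            raise ValueError(f"bad category {self.category!r}")
        if (self.cofactor is not None) != (self.category == "specific"):
            raise ValueError("cofactor must be set exactly for specific calls")


def residue_prevalence(msa: MultipleAlignment, column: int, residue: str) -> float:
    """Fraction of all rows (gap rows included in the denominator)
    carrying exactly ``residue`` at ``column``."""
    col = msa.column(column)  # raises IndexError when out of range
    return sum(1 for c in col if c == residue) / len(col)


def _rule_evidence(rule: CofactorRule, pairs: Iterable[tuple[str, str]],
                   msa: MultipleAlignment, element_map: ElementMap,
                   ) -> list[tuple[int, str, float]]:
    """Best (column, residue, prevalence) per (element, residue) pair; the
    best column for an element is the one with the highest prevalence.
    Pairs whose element has no mapped column get prevalence 0 at column -1."""
    out = []
    for element, residue in pairs:
        best: tuple[int, str, float] = (-1, residue, 0.0)
        for rep_pos in element_map.columns_for(element):
            col = msa.representative_columns.get(rep_pos)
            if col is None:
                continue
            prev = residue_prevalence(msa, col, residue)
            if prev > best[2]:
                best = (col, residue, prev)
        out.append(best)
    return out


def classify_cluster(profile: ConservationProfile, msa: MultipleAlignment,
                     element_map: ElementMap,
                     rules: Optional[Sequence[CofactorRule]] = None,
                     min_prevalence: float = 0.5) -> FunctionalCall:
    """Triage one cluster against the key-residue rules.

    A rule matches when every primary residue reaches the prevalence
    threshold at some column mapped to its element; among matching rules
    the highest mean primary prevalence wins, with mean secondary
    prevalence and then rule order as tie-breaks.  Without a match, the
    cluster is *possible* if any conserved position (conservation-module
    defaults) falls inside the cavity, else *unknown*.
    """
    if not element_map.columns:
        raise ElementMapError("cluster has no structural-element annotation")
    if rules is None:
        rules = builtin_rules()
    best = None
    for order, rule in enumerate(rules):
        threshold = rule.min_prevalence if rule.min_prevalence is not None else min_prevalence
        primary_ev = _rule_evidence(rule, rule.primary, msa, element_map)
        if any(prev < threshold for _, _, prev in primary_ev):
            continue
        secondary_ev = _rule_evidence(rule, rule.secondary, msa, element_map)
        primary_mean = sum(p for _, _, p in primary_ev) / len(primary_ev)
        secondary_mean = (sum(p for _, _, p in secondary_ev) / len(secondary_ev)
                          if secondary_ev else 0.0)
        key = (primary_mean, secondary_mean, -order)
        if best is None or key > best[0]:
            evidence = tuple(primary_ev) + tuple(
                ev for ev in secondary_ev if ev[2] >= threshold)
            best = (key, rule, evidence)
    if best is not None:
        _, rule, evidence = best
        call = FunctionalCall(category="specific", cofactor=rule.cofactor,
                              rule_name=rule.name, evidence=evidence)
        flags = classify_sequences(msa, call, rule)
        call.n_sequences_with_motif = sum(flags.values())
        return call

    cavity_alignment_cols = {
        msa.representative_columns[p] for p in element_map.cavity_columns
        if p in msa.representative_columns}
    conserved = conserved_positions(profile)
    cavity_hits = tuple((c, r, f) for c, r, f in conserved if c in cavity_alignment_cols)
    if cavity_hits:
        return FunctionalCall(category="possible", evidence=cavity_hits)
    return FunctionalCall(category="unknown")


def classify_sequences(msa: MultipleAlignment, call: FunctionalCall,
                       rule: CofactorRule) -> dict[str, bool]:
    """Per-sequence motif carriage for a specific call: does each row hold
    all primary residues of the matched rule at the evidence columns?"""
    if call.category != "specific":
        raise ValueError("classify_sequences needs a specific call")
    n_primary = len(rule.primary)
    primary_ev = call.evidence[:n_primary]
    flags = {}
    for rid, row in msa.rows.items():
        flags[rid] = all(col >= 0 and row[col] == res for col, res, _ in primary_ev)
    return flags


@dataclass(frozen=True)
class TriageSummary:
    """Sequence-weighted totals of the three triage categories."""

    n_specific: int
    n_possible: int
    n_unknown: int
    by_cofactor: Mapping[str, int]

    @property
    def total(self) -> int:
        return self.n_specific + self.n_possible + self.n_unknown


def triage_summary(calls: Mapping[int, FunctionalCall],
                   sizes: Mapping[int, int]) -> TriageSummary:
    """Aggregate per-cluster calls into sequence counts per category."""
    totals = {"specific": 0, "possible": 0, "unknown": 0}
    by_cofactor: dict[str, int] = {}
    for number, call in calls.items():
        n = sizes[number]
        totals[call.category] += n
        if call.category == "specific":
            by_cofactor[call.cofactor] = by_cofactor.get(call.cofactor, 0) + n
    return TriageSummary(n_specific=totals["specific"],
                         n_possible=totals["possible"],
                         n_unknown=totals["unknown"],
                         by_cofactor=by_cofactor)
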