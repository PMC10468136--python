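"""Taxonomy-normalized census of sensor-domain content across genomes.

Raw per-genome counts are not comparable across the tree of life because
genome sampling is wildly uneven (thousands of sequenced strains for some
species, one genome for whole phyla).  The census therefore normalizes
counts by total gene number (expressed as a percentage) and averages them
sequentially up the taxonomy — genomes within species, species within
genera, genera within families — so each family contributes a single
value no matter how densely it was sequenced.  Genome-size correlation is
assessed by Spearman rank correlation, with the sensor-protein count
subtracted from the gene count beforehand to avoid self-correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family_taxon", "genus", "species")


@dataclass(frozen=True)
class GenomeRecord:
    """One genome's lineage and sensor-domain content."""

    genome_id: str
    lineage: tuple[str, ...]
    gene_count: int
    pas_protein_count: int
    pas_domain_count: int
    domains_per_protein: Optional[tuple[int, ...]] = None
    isoforms: Optional[Mapping[str, tuple[tuple[str, int, bool], ...]]] = None
    #: protein/domain counts before isoform collapsing, where applicable
    pas_protein_count_with_isoforms: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS):
            raise ValueError(
                f"lineage must have {len(RANKS)} ranks {RANKS}, got {len(self.lineage)}")
        if min(self.gene_count, self.pas_protein_count, self.pas_domain_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.pas_protein_count > self.gene_count:
            raise ValueError("pas_protein_count cannot exceed gene_count")
        if self.pas_protein_count > 0 and self.pas_domain_count < self.pas_protein_count:
            raise ValueError("each sensor protein carries at least one domain")

    def rank(self, name: str) -> str:
        return self.lineage[RANKS.index(name)]


def collapse_isoforms(record: GenomeRecord) -> GenomeRecord:
    """Keep only the longest isoform per gene and recount.

    ``isoforms`` maps gene id -> tuple of (protein id, length, carries a
    sensor domain).  Length ties go to the lexicographically smallest
    protein id.  The pre-collapse sensor-protein count is retained in
    ``pas_protein_count_with_isoforms``.  Records without isoform data
    are returned unchanged.
    """
    if not record.isoforms:
        return record
    with_isoforms = sum(
        1 for isos in record.isoforms.values() for _, _, is_pas in isos if is_pas)
    kept_pas = 0
    for gene, isos in record.isoforms.items():
        if not isos:
            continue
        best = min(isos, key=lambda t: (-t[1], t[0]))
        if best[2]:
            kept_pas += 1
    return replace(record,
                   pas_protein_count=kept_pas,
                   pas_protein_count_with_isoforms=with_isoforms)


def normalize_counts(record: GenomeRecord) -> tuple[float, float]:
    """Percent of the gene complement that is sensor proteins / domains."""
    if record.gene_count <= 0:
        raise ValueError(f"genome {record.genome_id} has gene_count 0")
    return (100.0 * record.pas_protein_count / record.gene_count,
            100.0 * record.pas_domain_count / record.gene_count)


def _records_frame(records: Iterable[GenomeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if any(not label for label in r.lineage):
            logger.warning("genome %s excluded: missing rank label in lineage %r",
                           r.genome_id, r.lineage)
            continue
        protein_pct, domain_pct = normalize_counts(r)
        rows.append(dict(zip(RANKS, r.lineage), genome_id=r.genome_id,
                         protein_pct=protein_pct, domain_pct=domain_pct))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CensusTable:
    """Family-level normalized values plus per-kingdom summaries.

    ``family_table`` has one row per (kingdom, family); averaging stops at
    the family rank, so kingdom comparisons use the set of family values
    as the sample (one dot per family), not a grand mean.
    """

    family_table: pd.DataFrame
    kingdom_summary: pd.DataFrame


def hierarchical_average(records: Sequence[GenomeRecord]) -> CensusTable:
    """Sequential species -> genus -> family averaging of normalized counts."""
    frame = _records_frame(records)
    if frame.empty:
        raise ValueError("no usable genome records")
    values = ["protein_pct", "domain_pct"]
    species = frame.groupby(list(RANKS), as_index=False)[values].mean()
    genus = species.groupby(list(RANKS[:6]), as_index=False)[values].mean()
    family = genus.groupby(list(RANKS[:5]), as_index=False)[values].mean()
    kingdom_summary = (family.groupby("kingdom")[values]
                       .agg(["mean", "median", "std", "count"]))
    return CensusTable(family_table=family, kingdom_summary=kingdom_summary)


@dataclass(frozen=True)
class SpearmanResult:
    """Rank correlation of sensor content with genome size."""

    protein_rho: float
    protein_p: float
    domain_rho: float
    domain_p: float
    n: int


def correlate_genome_size(records: Sequence[GenomeRecord]) -> SpearmanResult:
    """Spearman correlation of (gene count − sensor-protein count) with the
    sensor protein and domain counts.

    Subtracting the sensor-protein count from the regressor removes the
    trivial self-correlation of a count with its own superset.  Raises
    ``ValueError`` on fewer than 3 records or constant input, where the
    coefficient is undefined.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a rank correlation")
    genes = np.array([r.gene_count - r.pas_protein_count for r in records], dtype=float)
    proteins = np.array([r.pas_protein_count for r in records], dtype=float)
    domains = np.array([r.pas_domain_count for r in records], dtype=float)
    for arr, label in [(genes, "adjusted gene counts"),
                       (proteins, "sensor protein counts"),
                       (domains, "sensor domain counts")]:
        if np.ptp(arr) == 0:
            raise ValueError(f"{label} are constant; Spearman rho is undefined")
    rho_p, p_p = stats.spearmanr(genes, proteins)
    rho_d, p_d = stats.spearmanr(genes, domains)
    return SpearmanResult(protein_rho=float(rho_p), protein_p=float(p_p),
                          domain_rho=float(rho_d), domain_p=float(p_d),
                          n=len(records))


def presence_by_phylum(records: Sequence[GenomeRecord],
                       min_proteomes: int = 20,
                       include_all: bool = False) -> pd.DataFrame:
    """Per (kingdom, phylum) counts of genomes with and without sensor
    domains, and the percentage with.  Phyla sampled below
    ``min_proteomes`` genomes are suppressed unless ``include_all``."""
    rows = []
    for r in records:
        rows.append({"kingdom": r.lineage[0], "phylum": r.lineage[1],
                     "has_pas": r.pas_domain_count >= 1})
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["kingdom", "phylum", "n_with", "n_without", "percent"])
    grouped = frame.groupby(["kingdom", "phylum"])["has_pas"].agg(["sum", "count"])
    out = pd.DataFrame({
        "n_with": grouped["sum"].astype(int),
        "n_without": (grouped["count"] - grouped["sum"]).astype(int),
    }).reset_index()
    out["percent"] = 100.0 * out["n_with"] / (out["n_with"] + out["n_without"])
    if not include_all:
        out = out[(out["n_with"] + out["n_without"]) >= min_proteomes]
    return out.reset_index(drop=True)


def domains_per_protein(records: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Per-kingdom distribution (mean, median, max, n) of sensor domains
    per sensor protein; kingdoms with no sensor proteins are omitted."""
    per_kingdom: dict[str, list[int]] = {}
    for r in records:
        if r.domains_per_protein:
            per_kingdom.setdefault(r.lineage[0], []).extend(r.domains_per_protein)
    rows = []
    for kingdom in sorted(per_kingdom):
        counts = np.array(per_kingdom[kingdom])
        rows.append({"kingdom": kingdom, "mean": float(counts.mean()),
                     "median": float(np.median(counts)), "max": int(counts.max()),
                     "n_proteins": len(counts)})
    return pd.DataFrame(rows, columns=["kingdom", "mean", "median", "max", "n_proteins"])
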