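"""File formats, configuration and end-to-end orchestration.

The pipeline composes the modules in the order the analysis runs at
scale: redundancy reduction -> similarity network -> Markov clustering ->
size numbering -> per-cluster star alignment and conservation profile ->
cofactor triage -> inter-cluster distances.  All intermediates use plain
text formats: FASTA for sequences, BLAST tabular (outfmt 6) for edges,
TSV for genome tables and element maps, JSON for the consolidated report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .census import GenomeRecord
from .cofactor import (ElementMap, ElementMapError, FunctionalCall,
                       builtin_rules, classify_cluster, triage_summary)
from .conservation import (center_star_align, conservation_profile,
                           conserved_positions, select_representative)
from .mcl import (ClusterSet, MclParams, cluster_summary, distance_matrix,
                  mcl_cluster)
from .similarity import (DomainSequence, EdgeRecord, SequenceError,
                         SimilarityGraph, build_network, raw_score_from_bits,
                         reduce_redundancy)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised for malformed input files, with the offending location."""


# ---------------------------------------------------------------------------
# FASTA

def _header_from_sequence(seq: DomainSequence) -> str:
    if seq.taxonomy:
        return f"{seq.id}|{';'.join(seq.taxonomy)}"
    return seq.id


def write_fasta(sequences: Sequence[DomainSequence], path: PathLike) -> None:
    """Write sequences wrapped at 60 columns.  Headers carry the id and,
    as a final |-separated field, the ;-joined taxonomy path."""
    records = [SeqRecord(Seq(s.residues), id=_header_from_sequence(s), description="")
               for s in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> list[DomainSequence]:
    """Read domain sequences; duplicate ids raise a FormatError naming
    the id.  Headers of the form ``family|index|lineage;...`` restore the
    taxonomy and family hint."""
    out: list[DomainSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        parts = header.split("|")
        taxonomy: tuple[str, ...] = ()
        family_hint = None
        if len(parts) >= 3 and ";" in parts[-1]:
            taxonomy = tuple(parts[-1].split(";"))
            seq_id = "|".join(parts[:-1])
        else:
            seq_id = header
        if len(seq_id.split("|")) >= 2:
            family_hint = seq_id.split("|")[0]
        if seq_id in seen:
            raise FormatError(f"duplicate FASTA id {seq_id!r} in {path}")
        seen.add(seq_id)
        residues = str(record.seq).upper()
        if not residues:
            raise FormatError(f"empty sequence for id {seq_id!r} in {path}")
        try:
            out.append(DomainSequence(id=seq_id, residues=residues,
                                      taxonomy=taxonomy, family_hint=family_hint))
        except SequenceError as exc:
            raise FormatError(str(exc)) from exc
    return out


# ---------------------------------------------------------------------------
# edge tables (BLAST tabular, outfmt 6 dialect)

EDGE_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                "qstart", "qend", "sstart", "send", "evalue", "bitscore")


def write_edges(graph: SimilarityGraph, path: PathLike) -> None:
    """Write the network's hits as 12-column BLAST tabular (1-based
    inclusive coordinates in the file)."""
    with open(path, "w") as fh:
        for key in sorted(graph.records):
            r = graph.records[key]
            qs, qe = r.query_range
            ss, se = r.subject_range
            fh.write("\t".join([
                r.query_id, r.subject_id, f"{r.pident:.1f}", str(r.length),
                str(r.mismatch), str(r.gapopen), str(qs + 1), str(qe),
                str(ss + 1), str(se), f"{r.evalue:.3g}", f"{r.bitscore:.4f}",
            ]) + "\n")


def read_edges(path: PathLike) -> SimilarityGraph:
    """Read an outfmt-6 table back into a similarity graph; edge weights
    are raw alignment scores recovered from the bit scores."""
    graph = SimilarityGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(EDGE_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(EDGE_COLUMNS)} columns, "
                    f"got {len(fields)}")
            try:
                record = EdgeRecord(
                    query_id=fields[0], subject_id=fields[1],
                    pident=float(fields[2]), length=int(fields[3]),
                    mismatch=int(fields[4]), gapopen=int(fields[5]),
                    query_range=(int(fields[6]) - 1, int(fields[7])),
                    subject_range=(int(fields[8]) - 1, int(fields[9])),
                    evalue=float(fields[10]), bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            weight = raw_score_from_bits(record.bitscore)
            graph.add_edge(record.query_id, record.subject_id, weight, record)
    return graph


# ---------------------------------------------------------------------------
# genome tables and element maps

GENOME_COLUMNS = ("genome_id", "kingdom", "phylum", "class", "order",
                  "family_taxon", "genus", "species", "gene_count",
                  "pas_protein_count", "pas_domain_count", "domains_per_protein")


def write_genomes(records: Sequence[GenomeRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENOME_COLUMNS) + "\n")
        for r in records:
            per_protein = ",".join(map(str, r.domains_per_protein or ()))
            fh.write("\t".join([r.genome_id, *r.lineage, str(r.gene_count),
                                str(r.pas_protein_count), str(r.pas_domain_count),
                                per_protein]) + "\n")


def read_genomes(path: PathLike) -> list[GenomeRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if tuple(header) != GENOME_COLUMNS:
            raise FormatError(f"{path}:1: unexpected genome table header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(GENOME_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(GENOME_COLUMNS)} columns, got {len(fields)}")
            try:
                per_protein = (tuple(int(x) for x in fields[11].split(","))
                               if fields[11] else None)
                records.append(GenomeRecord(
                    genome_id=fields[0], lineage=tuple(fields[1:8]),
                    gene_count=int(fields[8]), pas_protein_count=int(fields[9]),
                    pas_domain_count=int(fields[10]),
                    domains_per_protein=per_protein))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_element_maps(maps: Mapping[str, ElementMap], path: PathLike) -> None:
    """TSV of (family/cluster label, representative column, element,
    cavity flag)."""
    with open(path, "w") as fh:
        fh.write("label\tcolumn\telement\tcavity\n")
        for label in sorted(maps):
            emap = maps[label]
            for col in sorted(emap.columns):
                cavity = int(col in emap.cavity_columns)
                fh.write(f"{label}\t{col}\t{emap.columns[col]}\t{cavity}\n")


def read_element_maps(path: PathLike) -> dict[str, ElementMap]:
    columns: dict[str, dict[int, str]] = {}
    cavities: dict[str, set[int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != ["label", "column", "element", "cavity"]:
            raise FormatError(f"{path}:1: unexpected element map header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            label, col, element, cavity = fields
            try:
                columns.setdefault(label, {})[int(col)] = element
                if int(cavity):
                    cavities.setdefault(label, set()).add(int(col))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return {label: ElementMap(columns=cols,
                              cavity_columns=frozenset(cavities.get(label, set())))
            for label, cols in columns.items()}


# ---------------------------------------------------------------------------
# configuration and the consolidated run

@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the pipeline, with the study defaults."""

    identity_threshold: float = 0.8
    min_coverage: float = 0.8
    significance: float = 0.05
    inflation: float = 1.4
    min_cluster_size: int = 100
    min_prevalence: float = 0.5
    trim_max_col_gap: float = 0.9
    trim_min_row_coverage: float = 0.8
    sample_fraction: float = 0.01
    matrix: str = "BLOSUM62"
    gap_open: float = 11
    gap_extend: float = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "min_coverage", "min_prevalence",
                     "trim_max_col_gap", "trim_min_row_coverage", "sample_fraction"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.significance <= 0:
            raise ValueError("significance must be positive")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ClusterReport:
    """Per-cluster slice of the run report."""

    number: int
    size: int
    members: list[str]
    representative: str
    call: FunctionalCall
    conserved_positions: list[tuple[int, str, float]]


@dataclass
class RunReport:
    """Consolidated, JSON-serializable record of one pipeline run."""

    stage_counts: dict[str, int]
    membership: dict[str, str]
    cluster_sizes: list[int]
    clusters: list[ClusterReport]
    triage: dict
    distances: dict[str, float]
    large_cluster_coverage: float
    provenance: dict

    def to_json(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            raise TypeError(f"cannot serialize {type(obj)!r}")

        return json.dumps(dataclasses.asdict(self), default=default,
                          sort_keys=True, indent=1)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig,
                 sequences: Optional[Sequence[DomainSequence]] = None,
                 fasta_path: Optional[PathLike] = None,
                 element_maps: Optional[Mapping[str, ElementMap]] = None,
                 out_dir: Optional[PathLike] = None) -> RunReport:
    """Run the full sequence-analysis pipeline and return the report.

    ``element_maps`` is keyed by family label; a cluster is classified
    with the map of its representative's family (the id prefix before
    the first ``|``).  Clusters without a usable map are reported as
    ``unknown``.  With ``out_dir`` set, all intermediates are written.
    """
    if sequences is None:
        if fasta_path is None:
            raise ValueError("provide sequences or fasta_path")
        sequences = _stage("read_input")(read_fasta)(fasta_path)
    if not sequences:
        raise RuntimeError("pipeline stage 'read_input' failed: input FASTA is empty")
    stage_counts = {"input": len(sequences)}
    logger.info("input: %d sequences", len(sequences))

    representatives, redundancy_map = _stage("reduce_redundancy")(reduce_redundancy)(
        sequences, config.identity_threshold, config.matrix,
        config.gap_open, config.gap_extend)
    stage_counts["representatives"] = len(representatives)
    logger.info("redundancy reduction: %d representatives", len(representatives))

    graph = _stage("build_network")(build_network)(
        representatives, config.min_coverage, config.significance, None,
        config.matrix, config.gap_open, config.gap_extend)
    stage_counts["network_edges"] = graph.n_edges()
    logger.info("network: %d nodes, %d edges", graph.n_nodes(), graph.n_edges())

    clusters = _stage("mcl_cluster")(mcl_cluster)(
        graph, MclParams(inflation=config.inflation))
    stage_counts["clusters"] = clusters.n_clusters
    logger.info("MCL: %d clusters", clusters.n_clusters)

    by_id = {s.id: s for s in representatives}
    rules = builtin_rules()
    cluster_reports: list[ClusterReport] = []
    calls: dict[int, FunctionalCall] = {}
    for number in range(1, clusters.n_clusters + 1):
        members = sorted(clusters.members(number))
        rep_id = select_representative(members, graph)
        member_seqs = [by_id[m] for m in members]
        msa = center_star_align(member_seqs, rep_id, config.matrix,
                                config.gap_open, config.gap_extend)
        profile = conservation_profile(msa)
        conserved = [(c, r, round(f, 6)) for c, r, f in conserved_positions(profile)]
        family = rep_id.split("|")[0]
        emap = (element_maps or {}).get(family)
        if emap is None:
            call = FunctionalCall(category="unknown")
        else:
            try:
                call = classify_cluster(profile, msa, emap, rules,
                                        config.min_prevalence)
            except ElementMapError:
                call = FunctionalCall(category="unknown")
        calls[number] = call
        cluster_reports.append(ClusterReport(
            number=number, size=len(members), members=members,
            representative=rep_id, call=call, conserved_positions=conserved))

    sizes = {k + 1: s for k, s in enumerate(clusters.sizes)}
    triage = triage_summary(calls, sizes)
    dmat = distance_matrix(clusters, graph)
    distances = {}
    for i in range(1, clusters.n_clusters + 1):
        for j in range(i + 1, clusters.n_clusters + 1):
            distances[f"{i}-{j}"] = float(dmat.loc[i, j])
    summary = cluster_summary(clusters, config.min_cluster_size)

    report = RunReport(
        stage_counts=stage_counts,
        membership=redundancy_map,
        cluster_sizes=clusters.sizes,
        clusters=cluster_reports,
        triage={"n_specific": triage.n_specific, "n_possible": triage.n_possible,
                "n_unknown": triage.n_unknown,
                "by_cofactor": dict(triage.by_cofactor)},
        distances=distances,
        large_cluster_coverage=summary.coverage,
        provenance={
            "config": config.to_dict(),
            "seed": config.seed,
            "version": __version__,
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(representatives, out_dir / "representatives.fasta")
        write_edges(graph, out_dir / "edges.tsv")
        with open(out_dir / "clusters.tsv", "w") as fh:
            fh.write("sequence_id\tcluster\n")
            for node in sorted(clusters.membership):
                fh.write(f"{node}\t{clusters.membership[node]}\n")
        with open(out_dir / "report.json", "w") as fh:
            fh.write(report.to_json())
    return report
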