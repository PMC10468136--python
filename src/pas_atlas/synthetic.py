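"""Synthetic sequence families and genome tables with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* families of ~100-120 aa domain sequences, each diverged from a common
  ancestor by per-site substitution, with a subset of columns under
  10-fold reduced mutation (site-specific conservation) and, optionally,
  planted key residues at named structural-element positions.  A
  configurable fraction of members carries a randomized residue at the
  motif positions instead — mirroring real clusters where a key residue
  is conserved in only 50-90% of members;
* genome tables in which the number of sensor-domain proteins scales with
  the gene count plus overdispersed noise, over a synthetic 7-rank
  taxonomy.

Everything is deterministic given the global seed; each family draws from
its own stream (derived by hashing the family name) so adding a family
never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .census import GenomeRecord
from .cofactor import ElementMap
from .similarity import AMINO_ACIDS, DomainSequence

#: Column positions of the nine structural elements of the ~110-residue
#: synthetic domain scaffold.  Motifs in the standard fixture are planted
#: at these coordinates; the matching element map is emitted alongside.
ELEMENT_COLUMNS: dict[str, int] = {
    "Aβ": 8, "Bβ": 20, "Cα": 30, "Dα": 40, "Eα": 52,
    "Fα": 63, "Gβ": 78, "Hβ": 88, "Iβ": 100,
}

# Residues that, conserved at a given element, would satisfy some
# cofactor rule's primary requirement.  The standard fixture forbids these
# in the ancestor wherever a family does not deliberately plant them, so
# that ground-truth labels are not contaminated by chance motifs.
_PRIMARY_BY_ELEMENT: dict[str, frozenset[str]] = {
    "Fα": frozenset("HWC"),
    "Eα": frozenset("H"),
    "Bβ": frozenset("Y"),
    "Cα": frozenset("E"),
    "Dα": frozenset("C"),
}


class SyntheticError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic domain family.

    mutation_rate is the per-member, per-site substitution probability;
    columns in ``conserved_columns`` mutate at a tenth of that rate.
    ``motif`` maps column index -> required residue; a
    ``violation_rate`` fraction of members (an exact rounded count)
    carries a random non-motif residue there instead.  ``forbidden``
    excludes residues from the ancestor at given columns (used by the
    standard fixture to avoid planting motifs by chance).
    """

    name: str
    size: int = 40
    length: int = 110
    mutation_rate: float = 0.15
    conserved_columns: frozenset[int] = frozenset()
    motif: Mapping[int, str] = field(default_factory=dict)
    violation_rate: float = 0.0
    cofactor_label: str = "none"
    indel_rate: float = 0.0
    forbidden: Mapping[int, frozenset[str]] = field(default_factory=dict)
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for rate, label in [(self.mutation_rate, "mutation_rate"),
                            (self.violation_rate, "violation_rate"),
                            (self.indel_rate, "indel_rate")]:
            if not 0 <= rate <= 1:
                raise SyntheticError(f"{label} must be in [0, 1], got {rate}")
        if self.size < 1:
            raise SyntheticError("family size must be >= 1")
        if self.length < 20:
            raise SyntheticError("ancestor length must be >= 20")
        for col, res in self.motif.items():
            if not 0 <= col < self.length:
                raise SyntheticError(f"motif column {col} outside [0, {self.length})")
            if res not in AMINO_ACIDS:
                raise SyntheticError(f"motif residue {res!r} is not an amino acid")
        if self.cofactor_label not in ("heme", "FAD", "FMN", "PYP", "none"):
            raise SyntheticError(f"unknown cofactor label {self.cofactor_label!r}")


@dataclass
class GroundTruth:
    """Book-keeping emitted next to the generated sequences."""

    sequence_to_family: dict[str, str]
    family_to_cofactor: dict[str, str]
    motif_columns: dict[str, dict[int, str]]
    violators: dict[str, frozenset[str]]
    rng_seed: int


def _family_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _default_lineage(name: str, index: int) -> tuple[str, ...]:
    tag = f"P{index:02d}"
    return ("Bacteria", f"Phylum_{tag}", f"Class_{tag}", f"Order_{tag}",
            f"Family_{tag}", f"Genus_{tag}", name)


def generate_families(specs: Sequence[FamilySpec], seed: int,
                      ) -> tuple[list[DomainSequence], GroundTruth]:
    """Generate all families and the ground-truth tables.

    Each family: sample an ancestor uniformly over the amino acids
    (honouring per-column exclusions), substitute per member and per site
    at the family's rates, force motif residues on non-violators, draw a
    non-motif residue for the exact rounded fraction of violators, then
    apply single-residue indels if enabled (motif columns are never
    deleted).  Deterministic given ``seed``.
    """
    if not specs:
        raise SyntheticError("need at least one FamilySpec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SyntheticError("family names must be unique")
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    sequences: list[DomainSequence] = []
    truth = GroundTruth({}, {}, {}, {}, int(seed))
    for fam_idx, spec in enumerate(specs):
        rng = _family_rng(seed, spec.name)
        lineage = spec.lineage or _default_lineage(spec.name, fam_idx)

        ancestor = np.empty(spec.length, dtype=np.int8)
        for col in range(spec.length):
            banned = {AMINO_ACIDS.index(r) for r in spec.forbidden.get(col, ())}
            allowed = np.array([k for k in range(20) if k not in banned])
            ancestor[col] = rng.choice(allowed)

        rates = np.full(spec.length, spec.mutation_rate)
        if spec.conserved_columns:
            cols = np.array(sorted(spec.conserved_columns))
            rates[cols] = spec.mutation_rate / 10.0

        members = np.tile(ancestor, (spec.size, 1))
        mask = rng.random((spec.size, spec.length)) < rates[None, :]
        n_mut = int(mask.sum())
        if n_mut:
            # uniform over the 19 alternatives to the current residue
            draw = rng.integers(0, 19, size=n_mut)
            cur = members[mask]
            members[mask] = draw + (draw >= cur)

        n_viol = int(round(spec.violation_rate * spec.size))
        violators = set(rng.choice(spec.size, size=n_viol, replace=False)) if n_viol else set()
        for col, res in sorted(spec.motif.items()):
            res_idx = AMINO_ACIDS.index(res)
            members[:, col] = res_idx
            for i in sorted(violators):
                alt = int(rng.integers(0, 19))
                members[i, col] = alt + (alt >= res_idx)

        fam_ids = []
        for i in range(spec.size):
            residues = members[i]
            if spec.indel_rate > 0:
                residues = _apply_indels(residues, set(spec.motif), spec.indel_rate, rng)
            seq_id = f"{spec.name}|{i:03d}"
            fam_ids.append(seq_id)
            sequences.append(DomainSequence(
                id=seq_id,
                residues="".join(aa[residues]),
                taxonomy=lineage,
                family_hint=spec.name,
            ))
            truth.sequence_to_family[seq_id] = spec.name
        truth.family_to_cofactor[spec.name] = spec.cofactor_label
        truth.motif_columns[spec.name] = dict(spec.motif)
        truth.violators[spec.name] = frozenset(fam_ids[i] for i in sorted(violators))
    return sequences, truth


def _apply_indels(residues: np.ndarray, motif_columns: set[int],
                  rate: float, rng: np.random.Generator) -> np.ndarray:
    """Single-residue insertions/deletions, each at rate/2 per site.

    Motif columns are protected from deletion so the planted key residues
    survive; insertions shift coordinates, which the star alignment later
    absorbs back onto the representative scaffold.
    """
    out: list[int] = []
    for col, res in enumerate(residues):
        u = rng.random()
        if u < rate / 2 and col not in motif_columns:
            continue  # deletion
        out.append(int(res))
        if rate / 2 <= u < rate:
            out.append(int(rng.integers(0, 20)))  # insertion after this site
    if not out:  # pathological all-deleted case
        out = [int(residues[0])]
    return np.array(out, dtype=np.int8)


# ---------------------------------------------------------------------------
# genome tables


@dataclass(frozen=True)
class LineageShape:
    """Fan-out of the synthetic taxonomy below one kingdom."""

    n_phyla: int = 4
    families_per_phylum: int = 3
    genera_per_family: int = 2
    species_per_genus: int = 2


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for a synthetic genome table.

    ``pas_rate`` is the expected number of sensor-domain proteins per
    gene; ``noise`` is a gamma-Poisson dispersion (0 = deterministic
    mean).  ``domains_per_protein_distribution`` maps domain counts >= 1
    to probabilities (mean ~2 by default, as observed across kingdoms).
    """

    n_genomes: int = 200
    lineage_shape: Mapping[str, LineageShape] = field(default_factory=lambda: {
        "Bacteria": LineageShape(),
        "Archaea": LineageShape(n_phyla=2),
        "Eukaryota": LineageShape(n_phyla=3),
    })
    gene_count_range: tuple[int, int] = (1000, 8000)
    pas_rate: float = 0.01
    domains_per_protein_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.25, 3: 0.13, 4: 0.07, 5: 0.03, 6: 0.02})
    noise: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pas_rate < 0:
            raise SyntheticError("pas_rate must be >= 0")
        if self.gene_count_range[0] < 1 or self.gene_count_range[0] > self.gene_count_range[1]:
            raise SyntheticError("gene_count_range must satisfy 1 <= min <= max")
        if self.noise < 0:
            raise SyntheticError("noise must be >= 0")
        dist = self.domains_per_protein_distribution
        if not dist or min(dist) < 1 or abs(sum(dist.values()) - 1.0) > 1e-9:
            raise SyntheticError(
                "domains_per_protein_distribution must cover counts >= 1 and sum to 1")


def generate_genomes(spec: GenomeSpec) -> list[GenomeRecord]:
    """Draw genome records whose sensor-protein counts scale with gene count."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0x67656E]))
    kingdoms = sorted(spec.lineage_shape)
    dcounts = np.array(sorted(spec.domains_per_protein_distribution))
    dprobs = np.array([spec.domains_per_protein_distribution[k] for k in dcounts])
    records: list[GenomeRecord] = []
    for g in range(spec.n_genomes):
        kingdom = kingdoms[int(rng.integers(len(kingdoms)))]
        shape = spec.lineage_shape[kingdom]
        p = int(rng.integers(shape.n_phyla))
        f = int(rng.integers(shape.families_per_phylum))
        ge = int(rng.integers(shape.genera_per_family))
        sp = int(rng.integers(shape.species_per_genus))
        tag = kingdom[:3]
        lineage = (kingdom, f"{tag}_phy{p}", f"{tag}_phy{p}_cls", f"{tag}_phy{p}_ord",
                   f"{tag}_phy{p}_fam{f}", f"{tag}_phy{p}_fam{f}_gen{ge}",
                   f"{tag}_phy{p}_fam{f}_gen{ge}_sp{sp}")
        lo, hi = spec.gene_count_range
        gene_count = int(rng.integers(lo, hi + 1))
        mean = spec.pas_rate * gene_count
        if spec.noise == 0:
            n_prot = int(round(mean))
        elif mean == 0:
            n_prot = 0
        else:
            lam = rng.gamma(shape=1.0 / spec.noise, scale=mean * spec.noise)
            n_prot = int(rng.poisson(lam))
        n_prot = min(n_prot, gene_count)
        per_protein = tuple(int(x) for x in rng.choice(dcounts, size=n_prot, p=dprobs))
        records.append(GenomeRecord(
            genome_id=f"G{g:05d}",
            lineage=lineage,
            gene_count=gene_count,
            pas_protein_count=n_prot,
            pas_domain_count=int(sum(per_protein)),
            domains_per_protein=per_protein,
        ))
    return records


# ---------------------------------------------------------------------------
# the standard six-family fixture


def standard_family_specs(size: int = 40, length: int = 110,
                          mutation_rate: float = 0.15,
                          violation_rate: float = 0.1) -> list[FamilySpec]:
    """The six-family study fixture: two heme families (His at Fα and at
    Eα), an FAD family (Trp at Fα with secondary His/Asn), an FMN family
    (Cys at Fα with secondary Arg/Asn), a PYP family (Cys/Tyr/Glu) and a
    motif-free family with generic conserved columns."""
    if length <= max(ELEMENT_COLUMNS.values()):
        raise SyntheticError(
            f"length must exceed {max(ELEMENT_COLUMNS.values())} to hold the element scaffold")
    e = ELEMENT_COLUMNS
    extra = frozenset({10, 45, 70, 95})

    def spec(name, motif, cofactor, conserved=extra):
        forbidden = {}
        for elem, col in e.items():
            banned = _PRIMARY_BY_ELEMENT.get(elem, frozenset()) - {motif.get(col)}
            if banned:
                forbidden[col] = frozenset(banned)
        return FamilySpec(
            name=name, size=size, length=length, mutation_rate=mutation_rate,
            conserved_columns=frozenset(conserved) | frozenset(motif),
            motif=motif, violation_rate=violation_rate, cofactor_label=cofactor,
            forbidden=forbidden)

    return [
        spec("heme_Fa", {e["Fα"]: "H"}, "heme"),
        spec("heme_Ea", {e["Eα"]: "H"}, "heme"),
        spec("FAD", {e["Fα"]: "W", e["Eα"]: "H", e["Hβ"]: "N"}, "FAD"),
        spec("FMN", {e["Fα"]: "C", e["Eα"]: "R", e["Hβ"]: "N"}, "FMN"),
        spec("PYP", {e["Bβ"]: "Y", e["Cα"]: "E", e["Dα"]: "C"}, "PYP"),
        spec("orphan", {}, "none", conserved=frozenset({15, 35, 55, 75, 95})),
    ]


def standard_element_map() -> ElementMap:
    """Element annotation matching the standard fixture's scaffold, in
    representative-residue coordinates; helix columns line the cavity."""
    columns = {col: elem for elem, col in ELEMENT_COLUMNS.items()}
    cavity = frozenset(ELEMENT_COLUMNS[x] for x in ("Bβ", "Cα", "Dα", "Eα", "Fα"))
    return ElementMap(columns=columns, cavity_columns=cavity)


def standard_element_maps(specs: Sequence[FamilySpec]) -> dict[str, ElementMap]:
    """One element map per family (all share the scaffold of the fixture)."""
    return {s.name: standard_element_map() for s in specs}


def write_fixture(sequences: Sequence[DomainSequence], truth: GroundTruth,
                  genomes: Sequence[GenomeRecord], directory: str | Path,
                  element_maps: Optional[Mapping[str, ElementMap]] = None,
                  ) -> dict[str, Path]:
    """Write FASTA + TSV fixture files; round-trips through pipeline_io."""
    from . import pipeline_io as pio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": directory / "sequences.fasta",
        "truth": directory / "truth.tsv",
        "genomes": directory / "genomes.tsv",
    }
    pio.write_fasta(sequences, paths["sequences"])
    with open(paths["truth"], "w") as fh:
        fh.write("sequence_id\tfamily\tcofactor\tis_violator\n")
        for seq_id, fam in truth.sequence_to_family.items():
            viol = int(seq_id in truth.violators.get(fam, frozenset()))
            fh.write(f"{seq_id}\t{fam}\t{truth.family_to_cofactor[fam]}\t{viol}\n")
    pio.write_genomes(genomes, paths["genomes"])
    if element_maps is not None:
        paths["elements"] = directory / "elements.tsv"
        pio.write_element_maps(element_maps, paths["elements"])
    return paths
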