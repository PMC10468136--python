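# Methods

## Scope and model

`pas-atlas` reconstructs functional families of PAS sensor domains from
sequence alone and summarizes their genomic distribution. The package works at
desk scale: every stage that a database-scale analysis delegates to heuristic
tools (DIAMOND-style seeded search, CD-HIT, HipMCL, MAFFT, profile HMMs) is
implemented here with its exact small-scale counterpart, behind the same
filters and statistics. The synthetic-data module is first-class: it defines
the study conditions under which the pipeline's recovery claims are tested.

## Pairwise alignment and the similarity network

Local alignment is exact Smith–Waterman with affine gaps via Biopython's C
`PairwiseAligner` (BLOSUM62 default; a gap of length L costs 11 + L). `X`
scores 0 against everything. Scores are unique; among co-optimal tracebacks the
aligner's first enumeration is reported, so results are deterministic.

Two identity conventions are exposed because they serve different purposes:
`identity` = matches / alignment columns (reported in edge tables), and
`short_identity` = matches / min(sequence length), the convention of greedy
redundancy reduction, where a strict `identity > threshold` (default 0.8)
joins a sequence to the first qualifying representative in longest-first
order.

Significance at desk scale cannot reuse a database-wide E-value, so the
network filter is the per-pair Karlin–Altschul bound: with the gapped
BLOSUM62(11,1) constants λ = 0.267 and K = 0.041, a hit is kept when
`S_bit = (λS − ln K)/ln 2 ≥ log2(m·n/E)` with E = 0.05, and when the aligned
span covers >80% of the query in at least one direction. Both filters are
configurable, including a raw bit-score threshold. Random 100-mer pairs pass
the significance bound occasionally (as an E of 0.05 implies) but essentially
never the coverage bound; true family members pass both by a wide margin.

## Markov clustering

Classic MCL on the dense column-stochastic matrix: self-loops equal each
node's maximum incident weight (stabilizes attractors; isolated nodes get a
unit loop), expansion is matrix squaring, inflation is an elementwise power
(default r = 1.4) followed by column renormalization. Entries below 1e-5 are
pruned (each column's maximum is always retained) and the column renormalized,
so every iterate is stochastic to machine precision. Iteration stops when the
largest absolute entry change falls below 1e-6 (cap 200 rounds). Clusters are
read from attractor rows; overlapping attractor systems are merged by support
intersection, and any node reachable by several systems goes to the one with
the largest flow into it, ties to the earliest system — fully deterministic.
Clusters are then numbered 1..K by decreasing size, ties by smallest member
id. The inter-cluster distance is cross-edge count / (|A|·|B|) with undirected
edges; a `directed_hits` flag doubles the numerator for comparability with
tools that report both search directions (the statistic may then exceed 1).

## Representatives, alignment and conservation

The per-cluster representative is the network medoid (largest summed
within-cluster edge weight, ties to the smallest id) — the sequence the rest
of the cluster aligns to best, standing in for "best hit against the cluster
profile". The multiple alignment is center-star on that representative using
global Needleman–Wunsch with the same matrix and gap costs; "once a gap,
always a gap" merging gives a common coordinate system in which representative
residues map injectively to columns. Cofactor rules are anchored on the domain
scaffold, so motif lookup goes through that representative-column map and
insertions relative to the representative are deliberately outside it.

Information content per column is log2 20 − H(p) in bits over non-gap
residues; the gap fraction is reported separately (logo tools differ here;
this choice is explicit and tested). No small-sample correction is applied —
conservation calls use a prevalence threshold, not the IC value. A column is
"conserved" when its modal residue frequency is ≥0.5 and its gap fraction
≤0.5. The 0.5 prevalence default reflects that real clusters support cofactor
calls at 53–60% key-residue prevalence; it is configurable per rule.
Trimming removes columns with >90% gaps, then rows covering <80% of the
surviving columns, in that order (idempotent); emptied alignments raise an
explicit error. Cluster subsampling takes max(1, round(0.01·n)) members,
seeded.

## Cofactor rules and triage

Five built-in rules encode the key-residue signatures: heme via His at Fα
(FixL/DosP) or at Eα (Aer2); FAD via Trp at Fα with secondary His (Eα) and
Asn (Hβ); FMN via the LOV cysteine at Fα with secondary Arg and Asn; and the
PYP triad Tyr (Bβ), Glu (Cα), Cys (Dα), all three primary. The
element-to-column map is an input (curated from structures in real use;
emitted by the generator for synthetic data), never inferred from sequence.

A cluster is *specific* when every primary residue of some rule reaches the
prevalence threshold (prevalence counts gap rows in the denominator,
matching "x% of sequences in this cluster" phrasing) at a column mapped to the
stated element; among matching rules the highest mean primary prevalence wins,
then mean secondary prevalence, then rule order. Otherwise it is *possible* if
any conserved position falls inside the annotated cavity columns (the cavity
restriction is deliberate: conservation elsewhere on the scaffold says nothing
about ligand binding), else *unknown*. Per-sequence motif carriage is reported
for specific clusters. Fe–S-cluster and non-cofactor ligand rules are out of
scope: no positional definitions are established for them.

## Census

Per-genome sensor-protein and sensor-domain counts are normalized by total
gene count and expressed as percentages. Averaging is sequential — genomes
within species, species within genera, genera within families — and stops at
the family rank: kingdom-level comparisons keep the family values as the
sample (one value per family) rather than collapsing to a grand mean, so
kingdoms with very different sampling depths remain comparable. Genomes with a
missing rank label are excluded with a logged warning, not imputed. Spearman's
ρ (midrank ties, t-approximation p-value, via scipy) relates
(gene count − sensor-protein count) to the sensor protein and domain counts;
constant inputs raise rather than returning NaN. Phylum presence tables
suppress phyla with fewer than 20 proteomes by default. Isoform collapsing
keeps the longest isoform per gene (ties to the smallest protein id) and
retains the isoform-inclusive count alongside.

## Synthetic data: what it emulates, and what it does not

Each family diverges from one ancestor drawn uniformly over the 20 amino
acids; members substitute per site at `mutation_rate` (default 0.15), with
conserved columns at a tenth of that. Substitutions are uniform over the 19
alternatives — the pipeline under test needs divergence, not a realistic rate
matrix. Motif residues are forced except in an exact
`round(violation_rate · size)` subset of members, whose motif positions are
redrawn uniformly from the 19 non-motif residues; planted motif prevalence is
therefore exactly 1 − violation_rate, which makes prevalence-recovery tests
sharp rather than borderline. Indels (off by default) are single-residue
events applied after substitution; motif columns are never deleted, and the
star alignment re-anchors shifted coordinates. Each family draws from its own
RNG stream (hash of the family name mixed with the global seed), so adding a
family leaves the others byte-identical.

One deliberate departure from pure uniform ancestors in the shipped standard
fixture: at structural-element columns where a family does not plant a motif,
the ancestor may not draw a residue that is itself a primary key residue of
some rule (H/W/C at Fα, H at Eα, Y at Bβ, E at Cα, C at Dα). With per-member
divergence of 0.15, every ancestral residue remains at ~85% prevalence, so a
chance His at Fα would be indistinguishable from a planted heme site and the
ground-truth labels would be wrong, not merely noisy. The exclusion keeps
labels meaningful; all other columns are uniform.

Genome tables draw a 7-rank lineage (kingdom, phylum, class, order, family,
genus, species) from a configurable fan-out, a uniform gene count
(default 1,000–8,000), and a sensor-protein count with mean
`pas_rate · gene_count` (default rate 0.01) under gamma–Poisson noise
(dispersion 0.3; 0 gives the deterministic rounded mean). Domains per protein
follow a discrete distribution with mean ≈1.9 on {1..6}.

What passing tests therefore show: the pipeline recovers partitions, planted
key residues, prevalences and count scalings under realistic divergence and
noise. What they do not show: behaviour under domain architecture variation,
fragmentary sequences, compositional bias, rate heterogeneity across lineages,
or horizontally transferred outliers — real data properties the generator does
not emulate.

## Problem sizes and numerical choices

The standard study fixture is six families × 40 members × 110 residues
(two heme variants, FAD, FMN, PYP, one motif-free), violation 0.1, seed-driven
end to end; recovery and triage on it run in well under a minute. Prevalence
recovery uses 200-member families at violation 0.4; the census uses 200
genomes. These sizes make every acceptance property exact or
tightly-toleranced while keeping the whole suite fast. MCL tolerances:
pruning 1e-5, convergence 1e-6, stochasticity asserted at 1e-9. Alignment
oracle checks are exhaustive over all 4-letter-alphabet pairs at lengths ≤3
and sampled at lengths ≤8 (the full exhaustive set at length 8 is ~4×10⁹
pairs). Bit scores in edge files are written at 4 decimals; raw scores
recovered on read are accurate to ~1e-3.

## Known limitations

* All-vs-all exact alignment is O(n²·L²): practical to a few thousand
  sequences, not millions; the module boundaries match the scaled-up tools, so
  swapping in a heuristic search would not change any downstream interface.
* Center-star alignment is a 2-approximation; progressive aligners may place
  gaps differently in gap-rich clusters.
* The per-pair significance bound is not a database E-value; thresholds are
  comparable in role, not numerically.
* The triage is only as good as the element map: without curated
  structural-element coordinates for a cluster's representative, the cluster
  can only be reported as unknown.
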