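"""Isoform collapsing, normalization, hierarchical averaging, correlation."""

import numpy as np
import pytest

from pas_atlas.census import (GenomeRecord, collapse_isoforms,
                              correlate_genome_size, domains_per_protein,
                              hierarchical_average, normalize_counts,
                              presence_by_phylum)
from pas_atlas.synthetic import GenomeSpec, generate_genomes


def record(genome_id="G1", lineage=None, gene_count=1000,
           pas_protein_count=10, pas_domain_count=10, **kw):
    lineage = lineage or ("Bacteria", "P1", "C1", "O1", "F1", "G1", "S1")
    return GenomeRecord(genome_id=genome_id, lineage=tuple(lineage),
                        gene_count=gene_count,
                        pas_protein_count=pas_protein_count,
                        pas_domain_count=pas_domain_count, **kw)


def lineage(family, genus, species):
    return ("Bacteria", "P1", "C1", "O1", family, genus, species)


class TestCollapseIsoforms:
    def test_longest_isoform_kept(self):
        rec = record(pas_protein_count=2, pas_domain_count=2, isoforms={
            "gene1": (("p_short", 300, True), ("p_long", 450, True)),
        })
        out = collapse_isoforms(rec)
        assert out.pas_protein_count == 1
        assert out.pas_protein_count_with_isoforms == 2

    def test_length_tie_goes_to_smallest_protein_id(self):
        rec = record(pas_protein_count=1, pas_domain_count=1, isoforms={
            "gene1": (("p_b", 300, False), ("p_a", 300, True)),
        })
        out = collapse_isoforms(rec)
        assert out.pas_protein_count == 1  # p_a kept, carries the domain

    def test_no_isoform_data_returns_record_unchanged(self):
        rec = record()
        assert collapse_isoforms(rec) is rec


class TestNormalizeCounts:
    def test_percent_of_gene_complement(self):
        assert normalize_counts(record()) == (pytest.approx(1.0), pytest.approx(1.0))
        r = record(gene_count=5000, pas_protein_count=20, pas_domain_count=25)
        assert normalize_counts(r)[1] == pytest.approx(0.5)

    def test_zero_counts_allowed_zero_genes_not(self):
        assert normalize_counts(record(pas_protein_count=0,
                                       pas_domain_count=0)) == (0.0, 0.0)
        with pytest.raises(ValueError):
            normalize_counts(record(gene_count=0, pas_protein_count=0,
                                    pas_domain_count=0))


class TestHierarchicalAverage:
    def test_two_level_hand_computed_example(self):
        # genus X: species at 1% and 3% -> 2%; genus Y: 4%; family -> 3%
        records = [
            record("g1", lineage("F1", "X", "S1"), 1000, 10, 10),
            record("g2", lineage("F1", "X", "S2"), 1000, 30, 30),
            record("g3", lineage("F1", "Y", "S3"), 1000, 40, 40),
        ]
        table = hierarchical_average(records).family_table
        assert len(table) == 1
        assert table["protein_pct"].iloc[0] == pytest.approx(3.0)

    def test_duplicated_genome_in_same_species_changes_nothing(self):
        records = [
            record("g1", lineage("F1", "X", "S1"), 1000, 10, 10),
            record("g2", lineage("F1", "Y", "S2"), 1000, 30, 30),
        ]
        base = hierarchical_average(records).family_table
        dup = hierarchical_average(
            records + [record("g3", lineage("F1", "X", "S1"), 1000, 10, 10)]
        ).family_table
        assert base["protein_pct"].iloc[0] == pytest.approx(dup["protein_pct"].iloc[0])

    def test_single_lineage_passes_genome_value_through(self):
        records = [record("g1", lineage("F1", "X", "S1"), 2000, 10, 12)]
        table = hierarchical_average(records).family_table
        assert table["protein_pct"].iloc[0] == pytest.approx(0.5)
        assert table["domain_pct"].iloc[0] == pytest.approx(0.6)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        records = generate_genomes(GenomeSpec(n_genomes=60, rng_seed=2))
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = hierarchical_average(records).family_table
        b = hierarchical_average(shuffled).family_table
        assert a.equals(b)

    def test_family_value_bounded_by_genus_values(self):
        records = generate_genomes(GenomeSpec(n_genomes=120, rng_seed=3))
        table = hierarchical_average(records).family_table
        # recompute genus-level values independently with plain loops
        per_genus: dict[tuple, list[float]] = {}
        per_species: dict[tuple, list[float]] = {}
        for r in records:
            per_species.setdefault(r.lineage, []).append(normalize_counts(r)[0])
        for lin, vals in per_species.items():
            per_genus.setdefault(lin[:6], []).append(float(np.mean(vals)))
        genus_means = {k: float(np.mean(v)) for k, v in per_genus.items()}
        for _, row in table.iterrows():
            fam_key = tuple(row[["kingdom", "phylum", "class", "order",
                                 "family_taxon"]])
            vals = [v for k, v in genus_means.items() if k[:5] == fam_key]
            assert min(vals) - 1e-12 <= row["protein_pct"] <= max(vals) + 1e-12

    def test_missing_rank_excluded_with_warning(self, caplog):
        records = [
            record("g1", lineage("F1", "X", "S1"), 1000, 10, 10),
            record("g2", ("Bacteria", "P1", "", "O1", "F1", "Y", "S2"), 1000, 30, 30),
        ]
        with caplog.at_level("WARNING"):
            table = hierarchical_average(records).family_table
        assert table["protein_pct"].iloc[0] == pytest.approx(1.0)
        assert "g2" in caplog.text


class TestCorrelateGenomeSize:
    def test_monotone_data_gives_rho_one(self):
        records = [record(f"g{i}", lineage("F1", "X", f"S{i}"),
                          1000 * (i + 1), 5 * (i + 1), 5 * (i + 1))
                   for i in range(10)]
        result = correlate_genome_size(records)
        assert result.protein_rho == pytest.approx(1.0)
        assert result.domain_rho == pytest.approx(1.0)

    def test_half_genes_regressor_still_perfectly_ranked(self):
        # pas_protein_count = gene_count / 2 exactly: the adjusted
        # regressor is also gene_count / 2, so rho is 1 by construction
        records = [record(f"g{i}", lineage("F1", "X", f"S{i}"),
                          2000 + 2 * i, 1000 + i, 1000 + i)
                   for i in range(10)]
        assert correlate_genome_size(records).protein_rho == pytest.approx(1.0)

    def test_planted_association_recovered(self):
        for seed in range(10):
            records = generate_genomes(GenomeSpec(
                n_genomes=200, pas_rate=0.01, noise=0.3, rng_seed=seed))
            result = correlate_genome_size(records)
            assert result.protein_rho > 0
            assert result.protein_p < 0.01

    def test_null_calibration_on_independent_data(self):
        rng = np.random.default_rng(12345)
        small = 0
        for _ in range(100):
            genes = rng.integers(1000, 8000, size=200)
            pas = rng.poisson(30, size=200)
            records = [record(f"g{i}", lineage("F1", "X", f"S{i}"),
                              int(genes[i]), int(pas[i]), int(pas[i]))
                       for i in range(200)]
            if abs(correlate_genome_size(records).protein_rho) < 0.2:
                small += 1
        assert small >= 95

    def test_constant_input_signalled(self):
        records = [record(f"g{i}", lineage("F1", "X", f"S{i}"), 1000, 10, 10)
                   for i in range(5)]
        with pytest.raises(ValueError):
            correlate_genome_size(records)


class TestPresenceByPhylum:
    def make(self, phylum, n_with, n_without):
        recs = []
        for i in range(n_with):
            recs.append(record(f"{phylum}w{i}",
                               ("Bacteria", phylum, "C", "O", "F", "G", f"S{i}"),
                               1000, 1, 1))
        for i in range(n_without):
            recs.append(record(f"{phylum}o{i}",
                               ("Bacteria", phylum, "C", "O", "F", "G", f"T{i}"),
                               1000, 0, 0))
        return recs

    def test_small_phyla_suppressed_by_default(self):
        records = self.make("tiny", 10, 8) + self.make("big", 18, 2)
        table = presence_by_phylum(records)
        assert list(table["phylum"]) == ["big"]
        full = presence_by_phylum(records, include_all=True)
        assert set(full["phylum"]) == {"big", "tiny"}

    def test_percentages(self):
        table = presence_by_phylum(self.make("p", 93, 7))
        assert table["percent"].iloc[0] == pytest.approx(93.0)
        empty = presence_by_phylum(self.make("p", 0, 25))
        assert empty["percent"].iloc[0] == 0.0


class TestDomainsPerProtein:
    def test_summary_statistics(self):
        records = [record("g1", None, 1000, 3, 6, domains_per_protein=(1, 2, 3))]
        table = domains_per_protein(records)
        assert table["mean"].iloc[0] == pytest.approx(2.0)
        assert table["median"].iloc[0] == 2.0

    def test_extreme_multi_domain_protein(self):
        records = [record("g1", None, 1000, 1, 19, domains_per_protein=(19,))]
        assert domains_per_protein(records)["max"].iloc[0] == 19

    def test_no_sensor_proteins_is_empty_not_an_error(self):
        records = [record("g1", None, 1000, 0, 0)]
        assert domains_per_protein(records).empty


class TestGenomeRecordInvariants:
    def test_protein_count_cannot_exceed_genes(self):
        with pytest.raises(ValueError):
            record(gene_count=5, pas_protein_count=6, pas_domain_count=6)

    def test_domains_at_least_proteins(self):
        with pytest.raises(ValueError):
            record(pas_protein_count=5, pas_domain_count=3)

    def test_lineage_must_have_seven_ranks(self):
        with pytest.raises(ValueError):
            record(lineage=("Bacteria", "P1"))
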