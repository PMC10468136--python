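"""Representative selection, star alignment, conservation, trimming, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pas_atlas.conservation import (EmptyAlignmentError, MultipleAlignment,
                                    center_star_align, conservation_profile,
                                    conserved_positions, sample_cluster,
                                    select_representative, trim_alignment)
from pas_atlas.similarity import (AMINO_ACIDS, DomainSequence, SimilarityGraph,
                                  local_align)
from pas_atlas.synthetic import FamilySpec, generate_families

LOG2_20 = math.log2(20)


def msa_from_rows(rows, representative=None, rep_cols=None):
    return MultipleAlignment(rows=dict(rows), representative=representative,
                             representative_columns=rep_cols or {})


class TestSelectRepresentative:
    def test_singleton_cluster(self):
        g = SimilarityGraph()
        g.add_node("only")
        assert select_representative({"only"}, g) == "only"

    def test_star_hub_wins(self):
        g = SimilarityGraph()
        for leaf in ("b", "c", "d"):
            g.add_edge("hub", leaf, 5.0)
        g.add_edge("b", "c", 1.0)
        assert select_representative({"hub", "b", "c", "d"}, g) == "hub"

    def test_medoid_equals_brute_force_over_alignment_scores(self):
        spec = FamilySpec(name="f", size=5, length=40, mutation_rate=0.2)
        seqs, _ = generate_families([spec], seed=8)
        g = SimilarityGraph()
        for i in range(5):
            for j in range(i + 1, 5):
                score = local_align(seqs[i], seqs[j]).score
                if score > 0:
                    g.add_edge(seqs[i].id, seqs[j].id, score)
        ids = {s.id for s in seqs}
        brute = {}
        for s in seqs:
            brute[s.id] = sum(local_align(s, t).score for t in seqs if t.id != s.id)
        expected = min(ids, key=lambda i: (-brute[i], i))
        assert select_representative(ids, g) == expected


class TestCenterStarAlign:
    def seqs(self, residues_by_id):
        return [DomainSequence(id=k, residues=v) for k, v in residues_by_id.items()]

    def test_identical_members_align_without_gaps(self):
        members = self.seqs({"r": "MKTLVAGHWERTYPASDFGH",
                             "a": "MKTLVAGHWERTYPASDFGH"})
        msa = center_star_align(members, "r")
        assert set(msa.rows.values()) == {"MKTLVAGHWERTYPASDFGH"}
        assert msa.n_columns == 20

    def test_internal_deletion_gives_one_gap_row(self):
        ref = "MKTLVAGHWERTYPASDFGH"
        deleted = ref[:10] + ref[11:]
        msa = center_star_align(self.seqs({"r": ref, "a": deleted}), "r")
        assert msa.rows["r"] == ref
        assert msa.rows["a"].count("-") == 1
        assert len(msa.rows["a"]) == len(ref)

    def test_insertion_adds_column_and_keeps_rep_mapping(self):
        ref = "MKTLVAGHWERTYPASDFGH"
        inserted = ref[:10] + "W" + ref[10:]
        msa = center_star_align(self.seqs({"r": ref, "a": inserted}), "r")
        assert msa.n_columns == len(ref) + 1
        # representative residues are recoverable through the column map
        rebuilt = "".join(msa.rows["r"][msa.representative_columns[p]]
                          for p in range(len(ref)))
        assert rebuilt == ref

    def test_column_count_at_least_representative_length(self):
        spec = FamilySpec(name="f", size=6, length=50, mutation_rate=0.2,
                          indel_rate=0.05)
        seqs, _ = generate_families([spec], seed=4)
        msa = center_star_align(seqs, seqs[0].id)
        assert msa.n_columns >= 50

    def test_unknown_representative_rejected(self):
        with pytest.raises(ValueError):
            center_star_align(self.seqs({"a": "ACDE"}), "missing")


class TestConservationProfile:
    def test_invariant_column_reaches_max_information(self):
        msa = msa_from_rows({"a": "H", "b": "H", "c": "H"})
        profile = conservation_profile(msa)
        assert profile.information[0] == pytest.approx(LOG2_20, abs=1e-9)

    def test_half_split_column_loses_one_bit(self):
        msa = msa_from_rows({"a": "H", "b": "H", "c": "W", "d": "W"})
        profile = conservation_profile(msa)
        assert profile.information[0] == pytest.approx(LOG2_20 - 1, abs=1e-9)

    def test_uniform_column_has_zero_information(self):
        msa = msa_from_rows({f"s{i}": aa for i, aa in enumerate(AMINO_ACIDS)})
        profile = conservation_profile(msa)
        assert profile.information[0] == pytest.approx(0.0, abs=1e-9)

    def test_all_gap_column_reports_gap_fraction_one(self):
        msa = msa_from_rows({"a": "A-", "b": "C-"})
        profile = conservation_profile(msa)
        assert profile.gap_fraction[1] == 1.0
        assert profile.information[1] == 0.0

    @given(st.lists(st.sampled_from(AMINO_ACIDS), min_size=2, max_size=40),
           st.permutations(list(AMINO_ACIDS)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_information_bounds_and_relabeling_invariance(self, column, perm):
        mapping = dict(zip(AMINO_ACIDS, perm))
        msa = msa_from_rows({f"s{i}": c for i, c in enumerate(column)})
        relabeled = msa_from_rows({f"s{i}": mapping[c] for i, c in enumerate(column)})
        ic = conservation_profile(msa).information[0]
        ic_perm = conservation_profile(relabeled).information[0]
        assert 0.0 <= ic <= LOG2_20 + 1e-12
        assert ic == pytest.approx(ic_perm, abs=1e-9)


class TestConservedPositions:
    def test_sixty_percent_dominant_residue_is_reported(self):
        msa = msa_from_rows({f"s{i}": ("H" if i < 6 else "AWYCG"[i - 6]) for i in range(10)})
        hits = conserved_positions(conservation_profile(msa))
        assert hits == [(0, "H", pytest.approx(0.6))]

    def test_subthreshold_column_not_reported(self):
        msa = msa_from_rows({f"s{i}": c for i, c in enumerate("HHWWY")})
        assert conserved_positions(conservation_profile(msa)) == []

    def test_all_gap_column_never_reported(self):
        msa = msa_from_rows({"a": "-", "b": "-"})
        assert conserved_positions(conservation_profile(msa)) == []

    def test_planted_conserved_columns_recovered(self):
        conserved = frozenset({5, 20, 40, 70})
        motif = {30: "H", 55: "W"}
        spec = FamilySpec(name="f", size=100, length=80, mutation_rate=0.15,
                          conserved_columns=conserved | frozenset(motif),
                          motif=motif, violation_rate=0.1)
        seqs, _ = generate_families([spec], seed=11)
        msa = center_star_align(seqs, seqs[0].id)
        profile = conservation_profile(msa)
        hits = {col: freq for col, _, freq in conserved_positions(profile)}
        for col in conserved:
            assert msa.representative_columns[col] in hits
        for col, res in motif.items():
            freq = hits[msa.representative_columns[col]]
            assert abs(freq - 0.9) <= 0.05


class TestTrimAlignment:
    def test_hypergapped_column_removed(self):
        rows = {f"s{i}": ("A-" if i else "AC") for i in range(20)}
        trimmed = trim_alignment(msa_from_rows(rows))
        assert trimmed.n_columns == 1  # 95% gapped column dropped

    def test_low_coverage_row_removed(self):
        rows = {f"s{i}": "ACDEFGHIKL" for i in range(9)}
        rows["weak"] = "ACDEFGH---"  # covers 70% of retained columns
        trimmed = trim_alignment(msa_from_rows(rows))
        assert "weak" not in trimmed.rows

    def test_gap_free_alignment_unchanged(self):
        rows = {"a": "ACDEF", "b": "ACDEF"}
        trimmed = trim_alignment(msa_from_rows(rows))
        assert trimmed.rows == rows

    def test_idempotent(self):
        rows = {f"s{i}": "ACDEFGHIKL" for i in range(9)}
        rows["weak"] = "ACDEFG----"
        rows["gappy"] = "A---------"
        once = trim_alignment(msa_from_rows(rows))
        twice = trim_alignment(once)
        assert twice.rows == once.rows

    def test_emptied_alignment_signalled(self):
        # every column beyond the gap threshold
        with pytest.raises(EmptyAlignmentError):
            trim_alignment(msa_from_rows({"a": "--", "b": "-A"}), max_col_gap=0.4)
        # every row below the coverage threshold
        with pytest.raises(EmptyAlignmentError):
            trim_alignment(msa_from_rows({"a": "A-", "b": "-A"}))


class TestSampleCluster:
    def test_one_percent_of_a_thousand(self):
        members = [f"s{i}" for i in range(1000)]
        assert len(sample_cluster(members, 0.01, seed=0)) == 10

    def test_minimum_of_one(self):
        members = [f"s{i}" for i in range(50)]
        assert len(sample_cluster(members, 0.01, seed=0)) == 1

    def test_deterministic_and_without_replacement(self):
        members = [f"s{i}" for i in range(200)]
        a = sample_cluster(members, 0.05, seed=3)
        b = sample_cluster(members, 0.05, seed=3)
        assert a == b
        assert len(set(a)) == len(a) == 10
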