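import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pamprospector import ortholog as ort
from pamprospector import synthetic as syn
from pamprospector.errors import ConfigError, InputError, ValidationError
from pamprospector.records import ProteinRecord

from oracles import brute_align_score

AA = "ACDEFGHIKLMNPQRSTVWY"
protein_str = st.text(alphabet=AA, min_size=1, max_size=8)


class TestGlobalAlign:
    def test_identity_alignment_scores_100_percent(self):
        aln = ort.global_align(ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACDE"))
        assert aln.aligned_ref == aln.aligned_query == "ACDE"
        assert aln.percent_score == 100.0

    def test_matches_exhaustive_enumeration_on_classic_pair(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        aln = ort.global_align(ProteinRecord("a", a), ProteinRecord("b", b))
        assert aln.raw_score == brute_align_score(a, b)

    def test_gap_removal_recovers_inputs(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        aln = ort.global_align(ProteinRecord("a", a), ProteinRecord("b", b))
        assert aln.aligned_ref.replace("-", "") == a
        assert aln.aligned_query.replace("-", "") == b

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            ProteinRecord("a", "")
        # an empty query cannot even be constructed; the aligner also guards

    def test_unknown_matrix_is_config_error(self):
        with pytest.raises(ConfigError):
            ort.global_align(ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACDE"),
                             matrix="NOSUCH99")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(protein_str, protein_str)
    def test_optimality_against_recursion_oracle(self, a, b):
        """Alignment optimality: the engine's score equals exhaustive
        enumeration of all global alignments for short random pairs."""
        aln = ort.global_align(ProteinRecord("a", a), ProteinRecord("b", b))
        assert aln.raw_score == pytest.approx(brute_align_score(a, b))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(protein_str, protein_str)
    def test_score_symmetry(self, a, b):
        fwd = ort.global_align(ProteinRecord("a", a), ProteinRecord("b", b))
        rev = ort.global_align(ProteinRecord("b", b), ProteinRecord("a", a))
        assert fwd.raw_score == pytest.approx(rev.raw_score)


class TestPercentScore:
    def test_arithmetic_and_clamp(self):
        assert ort.percent_blosum_score(350, 700) == 50.0
        assert ort.percent_blosum_score(-10, 700) == 0.0
        with pytest.raises(InputError):
            ort.percent_blosum_score(10, 0)


class TestFilterOrthologs:
    def test_identical_copy_kept(self, reference_protein):
        copy = ProteinRecord("copy", reference_protein.sequence)
        result = ort.filter_orthologs([copy], reference_protein, threshold=70)
        assert result.kept == [copy] and not result.discarded

    def test_tiers_partition_at_threshold(self, reference_protein):
        """High-tier (~85%) members pass the 70% filter, low-tier (~55%) fail,
        and scores recomputed independently per member agree."""
        high, _ = syn.gen_ortholog_family(reference_protein, 10, 0.12, seed=1)
        low, _ = syn.gen_ortholog_family(reference_protein, 10, 0.35, seed=2)
        low = [ProteinRecord("low_" + r.id, r.sequence) for r in low]
        result = ort.filter_orthologs(high + low, reference_protein, threshold=70)
        assert result.kept == high
        assert result.discarded == low
        ref_self = ort.self_score(reference_protein)
        for rec in high + low:
            aln = ort.global_align(reference_protein, rec)
            assert result.scores[rec.id] == pytest.approx(
                ort.percent_blosum_score(aln.raw_score, ref_self))

    def test_partition_is_total_and_order_preserving(self, reference_protein):
        recs, _ = syn.gen_ortholog_family(reference_protein, 8, 0.2, seed=3)
        result = ort.filter_orthologs(recs, reference_protein, threshold=70)
        assert len(result.kept) + len(result.discarded) == len(recs)
        assert [r for r in recs if r in result.kept] == result.kept

    def test_threshold_above_100_keeps_nothing(self, reference_protein):
        copy = ProteinRecord("copy", reference_protein.sequence)
        result = ort.filter_orthologs([copy], reference_protein, threshold=101)
        assert not result.kept and result.discarded == [copy]

    def test_empty_input_warns_and_returns_empty(self, reference_protein, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            result = ort.filter_orthologs([], reference_protein)
        assert result.kept == [] and result.discarded == []
        assert "empty" in caplog.text


class TestResidueMapping:
    def test_identity_mapping(self):
        aln = ort.global_align(ProteinRecord("a", "ACDEF"), ProteinRecord("b", "ACDEF"))
        assert ort.map_reference_positions(aln, [3]) == [(3, "D")]

    def test_single_indel_column_walk(self):
        """Hand-constructed alignment with one deletion: positions map by a
        manual column walk, with GAP at the deleted position."""
        aln = ort.PairwiseAlignment(ref_id="r", query_id="q",
                                    aligned_ref="WACDW", aligned_query="W-CDW",
                                    raw_score=0.0, percent_score=0.0)
        mapped = ort.map_reference_positions(aln, [1, 2, 3, 4, 5])
        assert mapped == [(1, "W"), (None, None), (2, "C"), (3, "D"), (4, "W")]

    def test_insertion_in_query_shifts_positions(self):
        aln = ort.PairwiseAlignment(ref_id="r", query_id="q",
                                    aligned_ref="AC-DE", aligned_query="ACWDE",
                                    raw_score=0.0, percent_score=0.0)
        assert ort.map_reference_positions(aln, [3, 4]) == [(4, "D"), (5, "E")]

    def test_out_of_range_position_rejected(self):
        aln = ort.global_align(ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACDE"))
        with pytest.raises(InputError):
            ort.map_reference_positions(aln, [5])

    def test_roundtrip_reproduces_alignment_columns(self, reference_protein):
        """Mapping then reading the query residue reproduces the alignment
        column content for every mapped position."""
        query, _ = syn.gen_ortholog_family(reference_protein, 1, 0.2, seed=9)
        aln = ort.global_align(reference_protein, query[0])
        mapping = ort.residue_map(aln)
        qseq = query[0].sequence
        rpos = qpos = 0
        for rchar, qchar in aln.columns:
            if rchar != "-":
                rpos += 1
            if qchar != "-":
                qpos += 1
            if rchar != "-":
                if qchar == "-":
                    assert mapping[rpos] is None
                else:
                    assert mapping[rpos] == qpos
                    assert qseq[mapping[rpos] - 1] == qchar
        assert sorted(mapping) == list(range(1, len(reference_protein) + 1))


class TestResidueLogo:
    def test_identical_sequences_reach_max_information(self, reference_protein):
        copies = [ProteinRecord(f"c{i}", reference_protein.sequence)
                  for i in range(10)]
        profile = ort.build_residue_logo(copies, reference_protein, [200, 202],
                                         window=11)
        assert len(profile.window_positions) == 11
        assert np.allclose(profile.information_content, np.log2(20))

    def test_uniform_column_has_zero_information(self):
        ref = ProteinRecord("ref", AA)
        # 20 orthologs whose residue at position 10 cycles through all residues
        family = []
        for i, res in enumerate(AA):
            seq = list(AA)
            seq[9] = res
            family.append(ProteinRecord(f"o{i}", "".join(seq)))
        profile = ort.build_residue_logo(family, ref, [10], window=1)
        assert profile.information_content[10] == pytest.approx(0.0)

    def test_planted_contact_residues_are_counted(self, reference_protein):
        """Planted Q/Q in 2 of 20 members shows up as Q count = 2 at the
        contact columns, per the generator's truth record."""
        contacts = [200, 202]
        family, truth = syn.gen_ortholog_family(
            reference_protein, 20, 0.0, contacts,
            planted_residues={0: "QQ", 1: "QQ"}, seed=5)
        profile = ort.build_residue_logo(family, reference_protein, contacts)
        for pos in contacts:
            expected = sum(res[contacts.index(pos)] == "Q"
                           for res in truth.params["planted_residues"].values())
            ref_res = reference_protein.sequence[pos - 1]
            assert profile.frequency_table.loc[pos, "Q"] >= expected
            if ref_res != "Q":
                assert profile.frequency_table.loc[pos, "Q"] == expected

    def test_counts_sum_to_nongap_residues(self, reference_protein):
        family, _ = syn.gen_ortholog_family(reference_protein, 12, 0.15, seed=6)
        profile = ort.build_residue_logo(family, reference_protein, [180], window=5)
        for pos in profile.window_positions:
            nongap = (profile.residue_table[pos] != "-").sum()
            assert profile.frequency_table.loc[pos].sum() == nongap
        assert ((profile.information_content >= 0)
                & (profile.information_content <= np.log2(20) + 1e-12)).all()

    def test_even_window_is_config_error(self, reference_protein):
        with pytest.raises(ConfigError):
            ort.build_residue_logo([reference_protein], reference_protein,
                                   [200], window=10)


class TestHybridDesign:
    def test_junction_at_scaffold_end_returns_scaffold(self):
        s = ProteinRecord("s", "MKWVACDEFG")
        d = ProteinRecord("d", "MKWVACDEYY")
        design = ort.design_hybrid(s, d, junction_ref_pos=10, name="h")
        assert design.product_sequence == s.sequence

    def test_prefix_plus_donor_tail(self):
        s = ProteinRecord("s", "MKWVAAAAAA")
        d = ProteinRecord("d", "MKWVAACCCC")
        design = ort.design_hybrid(s, d, junction_ref_pos=6, name="h")
        assert design.product_sequence == "MKWVAACCCC"

    def test_point_mutation_applied_after_verification(self):
        s = ProteinRecord("s", "MRWVAAAAAA")
        design = ort.design_hybrid(s, s, junction_ref_pos=10,
                                   mutations=[("R", 2, "K")], name="h")
        assert design.product_sequence == "MKWVAAAAAA"

    def test_expected_residue_mismatch_names_position_and_found(self):
        s = ProteinRecord("s", "MGWVAAAAAA")
        with pytest.raises(ValidationError, match="position 2.*G"):
            ort.design_hybrid(s, s, junction_ref_pos=10,
                              mutations=[("R", 2, "K")], name="h")

    def test_variant_series_bookkeeping(self, reference_protein):
        """A scaffold+donor graft followed by efficiency then fidelity
        mutations, mirroring how engineered variant series are recorded."""
        donor, _ = syn.gen_ortholog_family(reference_protein, 1, 0.1, seed=11)
        ref = reference_protein
        base = ort.design_hybrid(ref, donor[0], junction_ref_pos=250, name="hybrid")
        pos = 30
        expected = base.product_sequence[pos - 1]
        new = "K" if expected != "K" else "R"
        improved = ort.design_hybrid(
            ref, donor[0], junction_ref_pos=250,
            mutations=[(expected, pos, new)], name="hybrid_i")
        assert improved.product_sequence[pos - 1] == new
        assert improved.product_sequence[:pos - 1] == base.product_sequence[:pos - 1]
        rec = improved.to_record()
        assert rec.id == "hybrid_i" and "junction=250" in rec.description
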