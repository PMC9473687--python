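"""Exon-annotated protein model: translation, renumbering, digestion, mapping."""

import numpy as np
import pytest

from titinsplice.errors import (
    AmbiguousMatchError,
    PeptideNotFoundError,
    StructuralError,
    UnmatchedExonError,
)
from titinsplice.exon_model import (
    build_exon_model,
    digest_tryptic,
    map_peptide_to_exons,
    renumber_exons,
)
from titinsplice.simulate import random_transcript

from conftest import model_from_protein


class TestBuildExonModel:
    def test_toy_translation_and_residue_annotation(self, toy_model):
        assert toy_model.protein == "MAK"
        assert toy_model.residue_exons == {1: frozenset({1}), 2: frozenset({1}), 3: frozenset({2})}
        assert toy_model.stop_codon_nt == 10

    def test_junction_codon_annotated_with_both_exons(self):
        m = build_exon_model("ATGGCTAAATAG", [(1, 4), (5, 12)])
        assert m.residue_exons[2] == frozenset({1, 2})  # codon GCT spans nts 4-6

    def test_gap_in_boundaries_is_structural_error(self):
        with pytest.raises(StructuralError):
            build_exon_model("ATGGCTAAATAG", [(1, 6), (8, 12)])

    def test_overlap_and_short_cds_rejected(self):
        with pytest.raises(StructuralError):
            build_exon_model("ATGGCTAAATAG", [(1, 7), (7, 12)])
        with pytest.raises(StructuralError):
            build_exon_model("ATG", [(1, 3)], cds_start=3)

    def test_protein_length_matches_cds(self):
        # no stop anywhere: protein length = floor(CDS length / 3)
        m = build_exon_model("ATGGCTAAAGCT", [(1, 12)])
        assert len(m.protein) == 4

    def test_json_round_trip(self, toy_model, tmp_path):
        from titinsplice.exon_model import ExonModel

        path = tmp_path / "model.json"
        toy_model.to_json(path)
        back = ExonModel.from_json(path)
        assert back.protein == toy_model.protein
        assert back.residue_exons == toy_model.residue_exons
        assert back.genomic_number == toy_model.genomic_number


class TestRenumberExons:
    def test_exact_sequence_matching(self):
        m = build_exon_model("ATGCCC", [(1, 3), (4, 6)])
        m2 = renumber_exons(m, genomic_exon_seqs=["ATG", "AAA", "CCC"])
        assert m2.genomic_number == {1: 1, 2: 3}
        # residue annotation follows the new numbering
        assert m2.residue_exons[2] == frozenset({3})

    def test_identity_mapping_table_changes_nothing(self, toy_model):
        m2 = renumber_exons(toy_model, mapping={1: 1, 2: 2})
        assert m2.genomic_number == toy_model.genomic_number
        assert m2.residue_exons == toy_model.residue_exons

    def test_unmatched_exon_errors_unless_allow_partial(self):
        m = build_exon_model("ATGGGG", [(1, 3), (4, 6)])
        with pytest.raises(UnmatchedExonError):
            renumber_exons(m, genomic_exon_seqs=["ATG", "CCC"])
        m2 = renumber_exons(m, genomic_exon_seqs=["ATG", "CCC"], allow_partial=True)
        assert m2.unmatched_exons == [2]

    def test_ambiguous_match_lists_candidates(self):
        m = build_exon_model("ATGCCC", [(1, 3), (4, 6)])
        with pytest.raises(AmbiguousMatchError):
            renumber_exons(m, genomic_exon_seqs=["CCC", "ATG", "CCC"])

    def test_exact_match_renumbering_is_idempotent(self):
        m = build_exon_model("ATGCCCAAA", [(1, 3), (4, 6), (7, 9)])
        genomic = ["ATG", "GGG", "CCC", "TTT", "AAA"]
        once = renumber_exons(m, genomic_exon_seqs=genomic)
        twice = renumber_exons(once, genomic_exon_seqs=genomic)
        assert once.genomic_number == twice.genomic_number == {1: 1, 2: 3, 3: 5}
        values = list(once.genomic_number.values())
        assert len(set(values)) == len(values)  # bijection onto its image


class TestDigestTryptic:
    def test_no_cleavage_before_proline(self):
        m = model_from_protein("MAKRPGK")
        assert [p.sequence for p in digest_tryptic(m, 0)] == ["MAK", "RPGK"]

    def test_protein_without_kr_is_single_peptide(self):
        m = model_from_protein("MAGHILW")
        assert [p.sequence for p in digest_tryptic(m, 0)] == ["MAGHILW"]

    def test_missed_cleavage_enumeration(self):
        m = model_from_protein("MAKRGK")
        seqs = {p.sequence for p in digest_tryptic(m, 1)}
        assert seqs == {"MAK", "R", "GK", "MAKR", "RGK"}

    def test_zero_missed_digest_reconstructs_protein(self, titin_model):
        peptides = digest_tryptic(titin_model, 0)
        assert "".join(p.sequence for p in peptides) == titin_model.protein

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_and_coverage_on_random_transcripts(self, seed):
        rng = np.random.default_rng(seed)
        seq, boundaries = random_transcript(rng, n_exons=int(rng.integers(2, 10)))
        model = build_exon_model(seq, boundaries)
        peptides = digest_tryptic(model, 0)
        assert "".join(p.sequence for p in peptides) == model.protein
        # union of peptide exon sets = union of residue annotations
        union = set()
        for p in peptides:
            union |= p.exon_set
        assert union == set(model.genomic_exons_covered)


class TestMapPeptideToExons:
    def test_unique_peptide_keeps_its_exon_annotation(self, titin_model):
        pep = next(
            p for p in digest_tryptic(titin_model, 0) if p.n_loci == 1 and len(p.sequence) >= 6
        )
        mapped = map_peptide_to_exons(pep.sequence, titin_model)
        assert mapped.exon_set == pep.exon_set
        assert mapped.n_loci == 1

    def test_junction_spanning_peptide(self):
        m = build_exon_model("ATGGCTAAATAG", [(1, 4), (5, 12)])
        mapped = map_peptide_to_exons("MAK", m)
        assert mapped.exon_set == frozenset({1, 2})

    def test_repeated_peptide_reports_loci_and_union(self):
        m = model_from_protein("MAGWKLLLRMAGWK")
        mapped = map_peptide_to_exons("MAGWK", m)
        assert mapped.n_loci == 2

    def test_absent_peptide_raises(self, toy_model):
        with pytest.raises(PeptideNotFoundError):
            map_peptide_to_exons("WWW", toy_model)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_substring_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq, boundaries = random_transcript(rng, n_exons=5, codons_per_exon=8)
        model = build_exon_model(seq, boundaries)
        protein = model.protein
        for start in range(0, len(protein) - 4, 7):
            pep = protein[start : start + 4]
            mapped = map_peptide_to_exons(pep, model)
            # brute force: scan every substring position
            hits = [i for i in range(len(protein) - 3) if protein[i : i + 4] == pep]
            expected = set()
            for h in hits:
                for r in range(h + 1, h + 5):
                    expected |= model.residue_exons[r]
            assert mapped.n_loci == len(hits)
            assert mapped.exon_set == frozenset(expected)
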