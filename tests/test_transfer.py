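import numpy as np
import pytest

from disorderome import (
    LocalAlignment,
    segment_similarity,
    smith_waterman,
    transfer_annotations,
)
from disorderome.io import LibraryEntry
from disorderome.synth import LibrarySpec, _mutate_to_identity, gen_library_with_queries, random_sequence

from oracles import sw_affine_score


class TestSmithWaterman:
    def test_identical_sequences_align_fully(self):
        aln = smith_waterman("ACDEFG", "ACDEFG")
        assert (aln.length, aln.n_identities) == (6, 6)

    def test_no_positive_pair_gives_empty_alignment(self):
        aln = smith_waterman("WWW", "PPP")
        assert aln == LocalAlignment.empty()

    def test_gap_cost_semantics(self):
        # 6 A-A matches (4 each) minus a 3-gap costing 10 + 0.5 * 2 = 11
        aln = smith_waterman("AAAWWWAAA", "AAAAAA")
        assert aln.score == pytest.approx(13.0)

    def test_score_matches_three_matrix_dp_oracle(self, rng):
        for _ in range(40):
            a = random_sequence(int(rng.integers(3, 31)), rng)
            b = random_sequence(int(rng.integers(3, 31)), rng)
            assert smith_waterman(a, b).score == pytest.approx(sw_affine_score(a, b))

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("AC1D", "ACD")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACD")


class TestSimilarity:
    def test_identical_ten_mers(self):
        aln = smith_waterman("ACDEFGHIKL", "ACDEFGHIKL")
        assert segment_similarity(aln, 10, 10) == pytest.approx(1.0)

    def test_worked_case_short_alignment(self):
        # 5 identities in a 5-column alignment of a 10-mer vs a 20-mer:
        # 5 / max(5, min(10, 20)) = 0.5
        aln = LocalAlignment("ACDEF", "ACDEF", 30.0, 5, 5)
        assert segment_similarity(aln, 10, 20) == pytest.approx(0.5)

    def test_empty_alignment_is_zero(self):
        assert segment_similarity(LocalAlignment.empty(), 5, 5) == 0.0

    def test_bounded_by_one(self, rng):
        for _ in range(50):
            a = random_sequence(int(rng.integers(5, 25)), rng)
            b = random_sequence(int(rng.integers(5, 25)), rng)
            aln = smith_waterman(a, b)
            assert 0.0 <= segment_similarity(aln, len(a), len(b)) <= 1.0

    def test_symmetric_on_homologous_pairs(self, rng):
        for _ in range(50):
            a = random_sequence(int(rng.integers(10, 40)), rng)
            b = _mutate_to_identity(a, 0.75, rng)
            fwd = segment_similarity(smith_waterman(a, b), len(a), len(b))
            rev = segment_similarity(smith_waterman(b, a), len(b), len(a))
            assert fwd == pytest.approx(rev)


class TestTransfer:
    LIB = [
        LibraryEntry("d1", "MKVLAWHHTE", "Flexible linkers/spacers"),
        LibraryEntry("d2", "CCCPGNNYYW", "Metal binding"),
    ]

    def test_identical_query_transfers_with_similarity_one(self):
        hits, census = transfer_annotations({"q": "MKVLAWHHTE"}, self.LIB)
        assert len(hits) == 1
        assert hits[0].similarity == pytest.approx(1.0)
        assert census == {"Flexible linkers/spacers": 1}

    def test_exact_threshold_does_not_fire(self):
        # two conservative substitutions keep a full-length 10-column
        # alignment with 8 identities: similarity exactly 0.8, no transfer
        query = "MKILAWHHSE"  # V->I, T->S
        aln = smith_waterman(query, "MKVLAWHHTE")
        assert (aln.length, aln.n_identities) == (10, 8)
        hits, _ = transfer_annotations({"q": query}, self.LIB)
        assert hits == []

    def test_census_counts_distinct_functions_per_segment(self):
        lib = [
            LibraryEntry("d1", "MKVLAWHHTE", "Metal binding"),
            LibraryEntry("d2", "MKVLAWHHTE", "Metal binding"),
            LibraryEntry("d3", "MKVLAWHHTE", "Phosphorylation"),
        ]
        hits, census = transfer_annotations({"q": "MKVLAWHHTE"}, lib)
        assert len(hits) == 3
        assert census == {"Metal binding": 1, "Phosphorylation": 1}

    def test_monotone_in_threshold(self, rng):
        sample = gen_library_with_queries(
            LibrarySpec(n_entries=30, n_queries=20, planted_fraction=0.5), 5
        )
        sizes = []
        for threshold in (0.5, 0.7, 0.9):
            hits, _ = transfer_annotations(sample.queries, sample.library, threshold=threshold)
            sizes.append(len(hits))
        assert sizes == sorted(sizes, reverse=True)

    def test_best_only_keeps_top_hit(self):
        lib = [
            LibraryEntry("d1", "MKVLAWHHTE", "Metal binding"),
            LibraryEntry("d2", "MKVLAWHHTW", "Phosphorylation"),
        ]
        hits, _ = transfer_annotations({"q": "MKVLAWHHTE"}, lib, best_only=True)
        assert len(hits) == 1 and hits[0].library_id == "d1"

    def test_empty_library_is_error(self):
        with pytest.raises(ValueError):
            transfer_annotations({"q": "MKVL"}, [])

    def test_planted_truth_recovered(self):
        sample = gen_library_with_queries(
            LibrarySpec(
                n_entries=40, n_queries=30, planted_fraction=0.4,
                planted_identity=0.9, decoy_identity=0.35,
            ),
            11,
        )
        hits, _ = transfer_annotations(sample.queries, sample.library)
        annotated = {}
        for h in hits:
            annotated.setdefault(h.query_id, set()).add(h.function)
        for qid, function in sample.truth.items():
            if function is None:
                assert qid not in annotated
            else:
                assert function in annotated.get(qid, set())
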