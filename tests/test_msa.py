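import numpy as np
import pytest

from disorderome import (
    ProteinRecord,
    Segment,
    call_variation,
    elm_census,
    group_by_cterm,
    lift_track,
    majority_profile,
    overlap_stats,
    project_track,
    segments_to_mask,
    variation_fractions,
)
from disorderome.msa import presence_matrix

from oracles import classify_column


def _msa(*rows):
    return [ProteinRecord(f"v{i}", row) for i, row in enumerate(rows)]


class TestLiftProject:
    def test_single_chain_lift_is_identity(self):
        msa = _msa("ACDEFG")
        membership = lift_track(msa, {"v0": [Segment(2, 4)]})
        assert list(np.flatnonzero(membership[0]) + 1) == [2, 3, 4]

    def test_gap_skipping(self):
        msa = _msa("A-C")
        membership = lift_track(msa, {"v0": [Segment(1, 2)]})
        assert list(membership[0]) == [True, False, True]

    def test_round_trip_on_generated_family(self, family):
        membership = lift_track(family.msa, family.chain_disorder)
        for v, rec in enumerate(family.msa):
            cols = [Segment(c + 1, c + 1) for c in np.flatnonzero(membership[v])]
            back = project_track(family.msa, rec.id, cols)
            assert back == family.chain_disorder[rec.id]

    def test_track_beyond_chain_names_chain(self):
        msa = _msa("AC-", "ACD")
        with pytest.raises(ValueError, match="v0"):
            lift_track(msa, {"v0": [Segment(1, 3)]})


class TestCallVariation:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AAAA", {"identical"}),
            ("AA-A", {"insertion"}),
            ("AC-A", {"insertion", "mutation"}),
            ("ACAA", {"mutation"}),
        ],
    )
    def test_column_classes(self, column, expected):
        msa = _msa(*(f"{ch}K" for ch in column))
        row = call_variation(msa).iloc[0]
        got = {name for name in ("identical", "mutation", "insertion") if row[name]}
        assert got == expected

    def test_matches_direct_classifier_on_random_msa(self, rng):
        for _ in range(30):
            n, L = int(rng.integers(2, 8)), int(rng.integers(5, 40))
            rows = [
                "".join(rng.choice(list("ACDE-"), size=L, p=[0.4, 0.2, 0.15, 0.05, 0.2]))
                for _ in range(n)
            ]
            rows = [r if r.strip("-") else "A" * L for r in rows]  # no all-gap rows
            table = call_variation(_msa(*rows))
            for c in range(L):
                letters = [r[c] for r in rows]
                expected = classify_column(letters)
                row = table.iloc[c]
                got = {k for k in ("identical", "mutation", "insertion") if row[k]}
                assert got == expected, f"column {letters}"

    def test_exact_partition_identity(self, family):
        # identical + gap-free mutation + insertion tile the columns exactly
        table = call_variation(family.msa)
        gapfree_mut = table["mutation"] & ~table["insertion"]
        total = table["identical"].sum() + gapfree_mut.sum() + table["insertion"].sum()
        assert total == len(table)

    def test_fractions_can_exceed_100(self):
        msa = _msa("AC-", "AAT", "A-T")
        fr = variation_fractions(call_variation(msa))
        assert fr["identical_pct"] + fr["mutation_pct"] + fr["insertion_pct"] > 100


class TestMajorityProfile:
    def test_unanimous_annotation(self):
        membership = np.ones((4, 6), dtype=bool)
        vote, segs = majority_profile(membership)
        assert segs == [Segment(1, 6)]
        assert np.allclose(vote, 1.0)

    def test_exactly_half_included(self):
        membership = np.zeros((100, 3), dtype=bool)
        membership[:50, 1] = True
        _, segs = majority_profile(membership)
        assert segs == [Segment(2, 2)]

    def test_just_below_half_excluded(self):
        membership = np.zeros((100, 1), dtype=bool)
        membership[:49, 0] = True
        _, segs = majority_profile(membership)
        assert segs == []

    def test_monotone_in_annotated_variants(self, rng):
        # with the denominator held fixed, annotating one more variant can
        # only grow the profile
        membership = rng.random((10, 40)) < 0.4
        vote_before, _ = majority_profile(membership)
        more = membership.copy()
        more[0] = True
        vote_after, _ = majority_profile(more)
        assert (vote_after >= vote_before).all()

    def test_present_only_denominator(self):
        # 3 of 10 chains carry a cassette and all annotate it: minority under
        # the all-variants rule, unanimous among present chains
        membership = np.zeros((10, 5), dtype=bool)
        presence = np.ones((10, 5), dtype=bool)
        presence[3:, 2] = False
        membership[:3, 2] = True
        _, segs_all = majority_profile(membership)
        _, segs_present = majority_profile(membership, presence=presence)
        assert segs_all == []
        assert segs_present == [Segment(3, 3)]


class TestOverlap:
    def test_subset_is_100(self):
        assert overlap_stats([Segment(2, 4)], [Segment(1, 10)], length=10) == pytest.approx(100.0)

    def test_disjoint_is_0(self):
        assert overlap_stats([Segment(1, 3)], [Segment(5, 8)], length=10) == pytest.approx(0.0)

    def test_empty_a_is_nan(self):
        assert np.isnan(overlap_stats([], [Segment(1, 2)], length=10))

    def test_matches_position_set_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(5, 60))
            mask_a = rng.random(L) < 0.4
            mask_b = rng.random(L) < 0.4
            set_a = set(np.flatnonzero(mask_a))
            set_b = set(np.flatnonzero(mask_b))
            got = overlap_stats(mask_a, mask_b)
            if not set_a:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(100.0 * len(set_a & set_b) / len(set_a))


class TestElmCensus:
    def test_interval_counts(self):
        census = elm_census({"LIG": [Segment(1, 3), Segment(5, 6), Segment(9, 12)], "CLV": []})
        assert census == {"LIG": 3, "CLV": 0}

    def test_adjacent_intervals_of_different_types_not_merged(self):
        census = elm_census({"LIG": [Segment(1, 3)], "MOD": [Segment(4, 6)]})
        assert census == {"LIG": 1, "MOD": 1}

    def test_generated_family_census_matches_truth(self, family):
        assert elm_census(family.elm_tracks) == family.truth["elm_counts"]


class TestVariantGrouping:
    def test_cterm_groups(self, family):
        groups = group_by_cterm(family.records)
        sizes = {tag: len(records) for tag, records in groups.items()}
        assert sizes == {"DEC": 3, "VYR": 3, "ERL": 2}

    def test_insertion_disorder_overlap_recovery(self, family):
        membership = lift_track(family.msa, family.chain_disorder)
        presence = presence_matrix(family.msa)
        _, segs = majority_profile(membership, presence=presence)
        disorder_mask = segments_to_mask(segs, family.insertion_mask.size)
        got = overlap_stats(family.insertion_mask, disorder_mask)
        assert got == pytest.approx(100.0 * family.truth["insertion_disorder_overlap"])
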