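import math

import numpy as np
import pytest

from disorderome import binarize, call_variation, extract_segments, summarize_protein, variation_fractions
from disorderome import synth
from disorderome.conservation import conservation_track


class TestDisorderCohort:
    def test_same_seed_gives_identical_cohort(self):
        spec = synth.DisorderCohortSpec(n_proteins=5, length_mean=200, length_sd=10)
        a = synth.gen_disorder_cohort(spec, 42)
        b = synth.gen_disorder_cohort(spec, 42)
        for ta, tb in zip(a.tracks, b.tracks):
            assert np.array_equal(ta.values, tb.values)
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]

    def test_zero_content_keeps_all_scores_ordered(self):
        spec = synth.DisorderCohortSpec(n_proteins=4, content=0.0, length_mean=150)
        cohort = synth.gen_disorder_cohort(spec, 1)
        for track in cohort.tracks:
            assert (track.values < 0.5).all()

    def test_thresholding_recovers_planted_segments_exactly(self):
        spec = synth.DisorderCohortSpec(n_proteins=10, length_mean=300, length_sd=30)
        cohort = synth.gen_disorder_cohort(spec, 9)
        for track in cohort.tracks:
            segs = extract_segments(binarize(track.values), 4)
            assert segs == cohort.truth_segments[track.protein_id]

    def test_planted_content_recovered(self):
        spec = synth.DisorderCohortSpec(n_proteins=80, content=0.18)
        cohort = synth.gen_disorder_cohort(spec, 2)
        summaries = [
            summarize_protein(t.protein_id, binarize(t.values)) for t in cohort.tracks
        ]
        assert np.median([s.content for s in summaries]) == pytest.approx(0.18, abs=0.02)

    def test_fully_disordered_rate(self):
        spec = synth.cytoplasmic_partner_spec(n_proteins=300, p_fully_disordered=0.2)
        cohort = synth.gen_disorder_cohort(spec, 3)
        rate = np.mean([
            summarize_protein(t.protein_id, binarize(t.values)).fully_disordered
            for t in cohort.tracks
        ])
        assert rate == pytest.approx(0.2, abs=0.08)

    def test_infeasible_content_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_disorder_cohort(synth.DisorderCohortSpec(content=0.95), 1)


class TestVariantFamily:
    def test_zero_variation_family(self):
        spec = synth.VariantFamilySpec(
            n_variants=5, parent_length=120, identical_frac=1.0, insertion_frac=0.0,
            mutation_frac=0.0, cterm_tags=(("DEC", 5),), elm_counts={},
            n_domains=0, n_morfs=0, background_disorder_frac=0.2,
        )
        fam = synth.gen_variant_family(spec, 3)
        fr = variation_fractions(call_variation(fam.msa))
        assert fr["identical_pct"] == pytest.approx(100.0)

    def test_planted_fractions_recovered_by_variation_caller(self):
        fam = synth.gen_variant_family(synth.VariantFamilySpec(), 8)
        fr = variation_fractions(call_variation(fam.msa))
        assert fr["identical_pct"] / 100 == pytest.approx(fam.truth["identical_frac"], abs=1e-9)
        assert fr["insertion_pct"] / 100 == pytest.approx(fam.truth["insertion_frac"], abs=1e-9)
        assert fr["mutation_pct"] / 100 == pytest.approx(fam.truth["mutation_frac"], abs=1e-9)

    def test_truth_near_requested_conditions(self):
        fam = synth.gen_variant_family(synth.VariantFamilySpec(), 8)
        assert fam.truth["identical_frac"] == pytest.approx(0.783, abs=0.01)
        assert fam.truth["insertion_frac"] == pytest.approx(0.164, abs=0.01)
        assert fam.truth["mutation_frac"] == pytest.approx(0.081, abs=0.01)
        assert fam.truth["insertion_disorder_overlap"] == pytest.approx(0.73, abs=0.02)

    def test_chain_tracks_consistent_with_column_disorder(self, family):
        # every chain's disorder track covers exactly the planted disorder
        # columns where the chain has residues
        from disorderome.msa import column_maps
        from disorderome.core import segments_to_mask

        maps = column_maps(family.msa)
        for v, rec in enumerate(family.msa):
            chain_mask = segments_to_mask(
                family.chain_disorder[rec.id], len(rec.ungapped)
            )
            present = maps[v] >= 0
            assert np.array_equal(chain_mask[maps[v, present]], family.disorder_mask[present])


class TestWop:
    def test_infinite_concentration_plants_background(self):
        sample = synth.gen_wop(synth.WopSpec(n_residues=30, concentration=math.inf, zero_row_rate=0.0), 5)
        assert np.allclose(sample.true_entropy, 0.0)
        est = conservation_track(sample.profile)
        assert np.nanmax(np.abs(est)) < 0.01

    def test_rows_sum_to_100_or_zero(self):
        sample = synth.gen_wop(synth.WopSpec(n_residues=100, zero_row_rate=0.3), 6)
        sums = sample.profile.wop.sum(axis=1)
        assert set(sums) <= {0, 100}

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_wop(synth.WopSpec(concentration=0.0), 1)


class TestLibrary:
    def test_perfect_identity_always_transfers(self):
        from disorderome import transfer_annotations

        sample = synth.gen_library_with_queries(
            synth.LibrarySpec(n_entries=15, n_queries=10, planted_fraction=1.0, planted_identity=1.0),
            4,
        )
        hits, _ = transfer_annotations(sample.queries, sample.library)
        assert {h.query_id for h in hits} == set(sample.queries)

    def test_label_distribution_shape(self, rng):
        sample = synth.gen_library_with_queries(synth.LibrarySpec(n_entries=600, n_queries=5), 9)
        from collections import Counter

        counts = Counter(e.function for e in sample.library)
        assert counts.most_common(1)[0][0] == "Protein-protein binding"

    def test_seed_required(self):
        with pytest.raises(ValueError):
            synth.gen_disorder_cohort(synth.DisorderCohortSpec(), None)
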