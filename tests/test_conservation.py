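import math

import numpy as np
import pytest

from disorderome import (
    BACKGROUND,
    ProteinRecord,
    Segment,
    average_conservation,
    conservation_track,
    region_mean_conservation,
    relative_entropy,
)
from disorderome.conservation import UNIFORM_BACKGROUND, lift_scores
from disorderome.io import WopProfile
from disorderome.synth import WopSpec, gen_wop


class TestRelativeEntropy:
    def test_identical_distributions_give_zero(self):
        assert relative_entropy(BACKGROUND, BACKGROUND) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_under_uniform_background(self):
        p = np.zeros(20)
        p[0] = 1.0
        assert relative_entropy(p, UNIFORM_BACKGROUND) == pytest.approx(math.log(20), abs=1e-9)

    def test_matches_termwise_summation_oracle(self, rng):
        for _ in range(200):
            p = rng.dirichlet(np.ones(20) * 0.5)
            q = rng.dirichlet(np.ones(20) * 2.0) + 1e-6
            q = q / q.sum()
            expected = sum(pi * math.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)
            assert relative_entropy(p, q) == pytest.approx(expected, abs=1e-9)

    def test_nonnegative_gibbs(self, rng):
        for _ in range(200):
            p = rng.dirichlet(np.ones(20))
            assert relative_entropy(p, BACKGROUND) >= -1e-12

    def test_base_conversion(self):
        p = np.zeros(20)
        p[3] = 1.0
        nats = relative_entropy(p, UNIFORM_BACKGROUND)
        bits = relative_entropy(p, UNIFORM_BACKGROUND, base=2)
        assert bits == pytest.approx(nats / math.log(2))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            relative_entropy(np.ones(20), BACKGROUND)  # sums to 20

    def test_undefined_row_gives_nan(self):
        assert math.isnan(relative_entropy(np.full(20, np.nan), BACKGROUND))


class TestConservationTrack:
    def test_zero_wop_rows_are_nan(self):
        wop = np.vstack([np.full(20, 5), np.zeros(20)])
        track = conservation_track(WopProfile("p", "AC", wop))
        assert not math.isnan(track[0]) and math.isnan(track[1])

    def test_estimates_close_to_generator_truth(self):
        sample = gen_wop(WopSpec(n_residues=200, zero_row_rate=0.0), 7)
        est = conservation_track(sample.profile)
        err = np.abs(est - sample.true_entropy)
        # integer-percent rounding perturbs sharp rows the most; errors stay
        # small in the median and bounded overall
        assert np.nanmedian(err) < 0.05
        assert np.nanmax(err) < 0.15


class TestAveraging:
    def _family(self):
        msa = [ProteinRecord("a", "ACD-F"), ProteinRecord("b", "ACDEF"), ProteinRecord("c", "A-DEF")]
        tracks = {"a": [1.0, 2.0, 3.0, 5.0], "b": [1.0, 2.0, 3.0, 4.0, 5.0], "c": [1.0, 3.0, 4.0, 5.0]}
        return msa, tracks

    def test_gaps_excluded_from_mean(self):
        msa, tracks = self._family()
        avg = average_conservation(msa, tracks)
        assert avg[1] == pytest.approx(2.0)  # chains a, b only
        assert avg[3] == pytest.approx(4.0)  # chains b, c only
        assert avg[4] == pytest.approx(5.0)

    def test_identical_tracks_average_to_single_track(self):
        msa = [ProteinRecord("a", "ACDEF"), ProteinRecord("b", "ACDEF")]
        values = [0.5, 1.5, 0.9, 2.0, 0.1]
        avg = average_conservation(msa, {"a": values, "b": values})
        assert np.allclose(avg, values)

    def test_single_variant_is_identity(self):
        msa = [ProteinRecord("a", "ACDEF")]
        avg = average_conservation(msa, {"a": [1, 2, 3, 4, 5]})
        assert np.allclose(avg, [1, 2, 3, 4, 5])

    def test_all_gap_column_is_nan(self):
        msa = [ProteinRecord("a", "A-C"), ProteinRecord("b", "A-C")]
        avg = average_conservation(msa, {"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert math.isnan(avg[1])

    def test_matches_per_column_mean_oracle(self, family, rng):
        tracks = {
            rec.id: rng.random(len(rec.ungapped)) for rec in family.msa
        }
        avg = average_conservation(family.msa, tracks)
        lifted = lift_scores(family.msa, tracks)
        for c in rng.integers(0, lifted.shape[1], size=50):
            col = lifted[:, c]
            vals = col[~np.isnan(col)]
            if vals.size:
                assert avg[c] == pytest.approx(vals.mean())
            else:
                assert math.isnan(avg[c])

    def test_length_mismatch_names_chain(self):
        msa = [ProteinRecord("a", "ACDEF")]
        with pytest.raises(ValueError, match="'a'"):
            average_conservation(msa, {"a": [1.0, 2.0]})


class TestRegionMeans:
    def test_constant_track(self):
        track = np.full(30, 1.3)
        assert region_mean_conservation(track, [Segment(5, 10)]) == pytest.approx(1.3)

    def test_whole_chain_equals_global_mean(self, rng):
        track = rng.random(50)
        assert region_mean_conservation(track) == pytest.approx(track.mean())

    def test_empty_region_set_is_nan(self):
        assert math.isnan(region_mean_conservation(np.ones(10), []))

    def test_partition_recombines_to_global_mean(self, rng):
        track = rng.random(60)
        parts = [Segment(1, 20), Segment(21, 45), Segment(46, 60)]
        weighted = sum(region_mean_conservation(track, [p]) * p.length for p in parts)
        assert weighted / 60 == pytest.approx(track.mean())
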