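import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrvibs import (
    InsufficientDataError,
    RRSeries,
    clean_rr,
    coarse_grain,
    ibs_distance,
    ibs_index,
    ibs_series,
    make_words,
    rank_table,
    segment_minutes,
    symbolize,
)
from hrvibs.ibs import IBSSeries, WordSequence
from hrvibs.synthetic import SyntheticProfile, generate_rr_series


class TestCoarseGrain:
    @pytest.mark.parametrize(
        "seg, s, expected",
        [
            ([0.800, 0.820, 0.810, 0.790], 2, [0.810, 0.800]),
            ([1, 2, 3, 4, 5], 2, [1.5, 3.5]),  # 5th element dropped: floor(5/2)=2
            ([1, 2, 3, 4, 5, 6], 3, [2.0, 5.0]),
        ],
    )
    def test_block_means(self, seg, s, expected):
        out = coarse_grain(seg, s)
        np.testing.assert_allclose(out.values, expected)
        assert out.n_prime == len(seg) // s

    def test_scale_one_identity(self, rng):
        seg = rng.random(17)
        np.testing.assert_array_equal(coarse_grain(seg, 1).values, seg)

    @pytest.mark.parametrize("s", [0, -1])
    def test_bad_scale(self, s):
        with pytest.raises(ValueError):
            coarse_grain([1.0, 2.0], s)

    def test_segment_shorter_than_scale(self):
        with pytest.raises(ValueError):
            coarse_grain([1.0, 2.0], 3)

    @given(n=st.integers(1, 60), s=st.integers(1, 9))
    @settings(deadline=None)
    def test_floor_length(self, n, s):
        if n < s:
            return
        seg = np.arange(n, dtype=float) + 1
        assert coarse_grain(seg, s).n_prime == n // s


class TestSymbolize:
    @pytest.mark.parametrize(
        "y, expected",
        [
            ([0.810, 0.800, 0.805, 0.805], [0, 1, 0]),  # fall, rise, tie->0
            ([1, 2, 3, 4], [1, 1, 1]),
            ([1, 1, 1], [0, 0]),
        ],
    )
    def test_increase_decrease_rule(self, y, expected):
        bits = symbolize(coarse_grain(y, 1))
        np.testing.assert_array_equal(bits, expected)

    def test_tie_symbol_one(self):
        bits = symbolize(coarse_grain([1.0, 1.0, 2.0, 1.0], 1), tie_symbol=1)
        np.testing.assert_array_equal(bits, [1, 1, 0])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            symbolize(coarse_grain([1.0], 1))


class TestMakeWords:
    @pytest.mark.parametrize(
        "bits, m, expected",
        [
            ([0, 1, 0], 2, [1, 2]),
            ([1, 1, 1, 1], 2, [3, 3, 3]),
            ([0, 1, 1, 0], 3, [3, 6]),
        ],
    )
    def test_big_endian_windows(self, bits, m, expected):
        out = make_words(np.array(bits), m)
        np.testing.assert_array_equal(out.words, expected)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            make_words(np.array([0, 1]), 3)

    @pytest.mark.parametrize("m", [2, 3])
    def test_exhaustive_count_oracle(self, m):
        """Sliding-window counts equal enumeration for ALL strings length<=10."""
        for n in range(m, 11):
            for bits in itertools.product([0, 1], repeat=n):
                words = make_words(np.array(bits), m).words
                # oracle: explicit enumeration of every window
                expected = [
                    int("".join(map(str, bits[i : i + m])), 2)
                    for i in range(n - m + 1)
                ]
                np.testing.assert_array_equal(words, expected)
                assert len(words) == n - m + 1
                assert np.all(words < 2**m)


def ws(codes, m=2):
    return WordSequence(words=np.asarray(codes), word_length=m)


def oracle_weights(words1, words2):
    """Term-by-term Shannon normalization over the union vocabulary."""
    vocab = sorted(set(words1) | set(words2))
    terms = []
    for x in vocab:
        h = 0.0
        for seq in (words1, words2):
            p = list(seq).count(x) / len(seq)
            if p > 0:
                h += -p * math.log(p)
        terms.append(h)
    total = sum(terms)
    return {x: t / total for x, t in zip(vocab, terms)}


class TestRankTable:
    def test_symmetric_sequences_share_weights(self):
        t = rank_table(ws([1, 2, 1, 2]), ws([1, 2, 1, 2]))
        assert t.n_words == 2
        np.testing.assert_allclose(t.p1, [0.5, 0.5])
        np.testing.assert_allclose(t.p2, [0.5, 0.5])
        np.testing.assert_allclose(t.weights, [0.5, 0.5])
        np.testing.assert_array_equal(t.k1, t.k2)

    def test_absent_word_ranked_bottom(self):
        t = rank_table(ws([3, 3, 3]), ws([0, 0, 0]))
        assert t.n_words == 2
        i3 = list(t.vocabulary).index(3)
        i0 = list(t.vocabulary).index(0)
        assert t.k1[i3] == 1 and t.k1[i0] == 2
        assert t.k2[i0] == 1 and t.k2[i3] == 2

    def test_weights_match_oracle(self, rng):
        w1 = rng.integers(0, 4, 50)
        w2 = rng.integers(0, 4, 50)
        t = rank_table(ws(w1), ws(w2))
        expected = oracle_weights(list(w1), list(w2))
        for x, w in zip(t.vocabulary, t.weights):
            assert w == pytest.approx(expected[int(x)], abs=1e-12)

    def test_empty_sequence_errors(self):
        with pytest.raises(InsufficientDataError):
            rank_table(ws([]), ws([1, 2]))

    @given(
        w1=st.lists(st.integers(0, 3), min_size=1, max_size=40),
        w2=st.lists(st.integers(0, 3), min_size=1, max_size=40),
    )
    @settings(deadline=None)
    def test_invariants(self, w1, w2):
        t = rank_table(ws(w1), ws(w2))
        assert t.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(t.weights >= 0)
        assert sorted(t.k1) == list(range(1, t.n_words + 1))
        assert sorted(t.k2) == list(range(1, t.n_words + 1))
        assert t.p1.sum() == pytest.approx(1.0, abs=1e-12)
        assert t.p2.sum() == pytest.approx(1.0, abs=1e-12)


class TestIbsDistance:
    def test_identical_sequences_zero(self, rng):
        w = rng.integers(0, 4, 30)
        assert ibs_distance(rank_table(ws(w), ws(w))) == 0.0

    def test_hand_enumerated_reversed_ranks(self):
        # L=2, fully reversed ranks, equal weights: D = (1*0.5 + 1*0.5)/2
        t = rank_table(ws([3, 3, 3]), ws([0, 0, 0]))
        assert ibs_distance(t) == pytest.approx(0.5)

    @given(
        w1=st.lists(st.integers(0, 7), min_size=2, max_size=40),
        w2=st.lists(st.integers(0, 7), min_size=2, max_size=40),
    )
    @settings(deadline=None)
    def test_symmetry_and_bounds(self, w1, w2):
        d12 = ibs_distance(rank_table(ws(w1, 3), ws(w2, 3)))
        d21 = ibs_distance(rank_table(ws(w2, 3), ws(w1, 3)))
        L = len(set(w1) | set(w2))
        assert d12 == pytest.approx(d21, abs=1e-14)
        assert 0.0 <= d12 <= (L - 1) / L + 1e-14


class TestIbsSeries:
    def _segments_from(self, iv):
        return segment_minutes(RRSeries("x", iv, cleaned=True))

    def test_identical_segments_give_zeros(self, rng):
        minute = 0.7 + 0.2 * rng.random(80)
        minute = minute * (59.9 / minute.sum())
        segs = self._segments_from(np.tile(minute, 3))
        out = ibs_series(segs)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_length_is_nsegments_minus_one(self, rng):
        iv = 0.6 + 0.4 * rng.random(400)
        segs = self._segments_from(iv)
        assert ibs_series(segs).n_values == len(segs) - 1

    def test_two_segments_needed(self, rng):
        iv = 0.8 + 0.05 * rng.random(100)  # ~82 s -> exactly one segment
        segs = self._segments_from(iv)
        assert len(segs) == 1
        with pytest.raises(InsufficientDataError):
            ibs_series(segs)

    def test_values_in_unit_interval(self, rng):
        iv = 0.6 + 0.4 * rng.random(1000)
        out = ibs_series(self._segments_from(iv))
        assert np.all((out.values >= 0) & (out.values < 1))

    def test_periodic_record_scores_below_noise_record(self):
        """Repeated fluctuation patterns give similar rank orders (lower IBS)."""
        periodic = generate_rr_series(
            SyntheticProfile(noise_sd=0.005, pattern_repeat="periodic",
                             repeat_minutes=1.0, duration=600, seed=5)
        )
        noisy = generate_rr_series(
            SyntheticProfile(noise_sd=0.03, pattern_repeat="none",
                             duration=600, seed=5)
        )
        def idx(rec):
            return ibs_index(ibs_series(segment_minutes(clean_rr(rec))))
        assert idx(periodic) <= idx(noisy)


class TestIbsIndex:
    @pytest.mark.parametrize("values, expected", [([0, 0], 0.0), ([0.2, 0.4], 0.3)])
    def test_mean(self, values, expected):
        s = IBSSeries("x", np.asarray(values, dtype=float))
        assert ibs_index(s) == pytest.approx(expected)

    def test_empty_gives_nan(self):
        assert math.isnan(ibs_index(IBSSeries("x", np.array([]))))
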