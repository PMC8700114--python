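"""Information-based similarity (IBS) between adjacent 1-minute RR segments.

Each segment is reduced to its fluctuation *pattern*: non-overlapping mean
coarse-graining at scale ``s`` (blocks of ``s`` beats replaced by their
mean), binarisation of successive increases (1) and decreases (0), and a
sliding window of width ``m`` over the bit string giving a sequence of m-bit
words.  Two adjacent segments are then compared through the rank order of
their word frequencies: words that are important (high Shannon information)
in either sequence weigh more, and the distance is the weighted mean rank
displacement

    D(R1, R2) = sum_i |K1(x_i) - K2(x_i)| * w(x_i) / L

over the joint vocabulary of L words, with entropy weights

    w(x_i) = (h1(x_i) + h2(x_i)) / sum_j (h1(x_j) + h2(x_j)),
    h(x) = -p(x) * log p(x)   (natural log, 0 log 0 := 0).

D is symmetric, zero for identical word sequences, and bounded by
(L-1)/L < 1.  Applied to every adjacent segment pair of a 24-h record this
yields the IBS series u(1..N), N = n_segments - 1; its mean is the record's
IBS index.  Small distances mean the heart-rate fluctuation pattern repeats
from one minute to the next — the reduced-variability signature of CHF — so
CHF records score a *lower* IBS index than normal ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io_rr import InsufficientDataError
from .preprocess import SegmentSet

__all__ = [
    "CoarseSeries", "WordSequence", "WordRankTable", "IBSSeries",
    "coarse_grain", "symbolize", "make_words", "rank_table",
    "ibs_distance", "ibs_series", "ibs_index",
]

logger = logging.getLogger(__name__)

DEFAULT_WORD_LENGTH = 2  # m
DEFAULT_SCALE = 2        # s


@dataclass(frozen=True)
class CoarseSeries:
    """Coarse-grained segment: block means at scale ``s``; n' = floor(n/s)."""

    values: np.ndarray
    scale: int

    @property
    def n_prime(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class WordSequence:
    """Sliding-window m-bit words as decimal codes in [0, 2^m)."""

    words: np.ndarray
    word_length: int


@dataclass(frozen=True)
class WordRankTable:
    """Joint word vocabulary of a segment pair with probabilities, ranks, weights.

    ``vocabulary`` is the union of distinct codes (ascending); ranks are 1-based
    by descending frequency within each sequence, ties broken by ascending
    code, absent words (frequency 0) ranked at the bottom under the same rule.
    Weights are the normalised Shannon terms and sum to 1.
    """

    vocabulary: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    weights: np.ndarray

    @property
    def n_words(self) -> int:
        return int(self.vocabulary.size)


@dataclass(frozen=True)
class IBSSeries:
    """Adjacent-segment IBS distances over one record; the u(t) fed to fApEn."""

    record_id: str
    values: np.ndarray

    @property
    def n_values(self) -> int:
        return int(self.values.size)


def coarse_grain(segment: Sequence[float] | np.ndarray, s: int) -> CoarseSeries:
    """Non-overlapping block means at scale ``s``; trailing remainder dropped."""
    seg = np.asarray(segment, dtype=float)
    if s < 1:
        raise ValueError(f"coarse-grain scale must be >= 1, got {s}")
    if seg.size < s:
        raise ValueError(
            f"segment of {seg.size} beats is shorter than scale {s}"
        )
    n_prime = seg.size // s
    values = seg[: n_prime * s].reshape(n_prime, s).mean(axis=1)
    return CoarseSeries(values=values, scale=int(s))


def symbolize(
    coarse: CoarseSeries, *, tie_symbol: Literal[0, 1] = 0
) -> np.ndarray:
    """Binary increase(1)/decrease(0) sequence of length n' - 1.

    A tie (no change) maps to ``tie_symbol``; the deterministic completion of
    the increase/decrease rule defaults to "not an increase" -> 0.
    """
    y = coarse.values
    if y.size < 2:
        raise InsufficientDataError(
            f"coarse series of length {y.size} cannot be symbolised"
        )
    up = y[1:] > y[:-1]
    if tie_symbol == 0:
        return up.astype(np.int8)
    down = y[1:] < y[:-1]
    return (~down).astype(np.int8)


def make_words(bits: np.ndarray, m: int) -> WordSequence:
    """Sliding window of width ``m``, stride 1, read big-endian as decimals."""
    bits = np.asarray(bits, dtype=np.int64)
    if m < 1:
        raise ValueError(f"word length must be >= 1, got {m}")
    if bits.size < m:
        raise InsufficientDataError(
            f"bit sequence of length {bits.size} is shorter than word length {m}"
        )
    powers = 1 << np.arange(m - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(bits, m)
    return WordSequence(words=windows @ powers, word_length=int(m))


def _counts_over(vocab: np.ndarray, words: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(vocab, words)
    return np.bincount(idx, minlength=vocab.size).astype(float)


def _ranks(vocab: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """1-based ranks by descending count, ties broken by ascending code."""
    # vocab is ascending, so a stable sort on -counts realises the tie-break
    order = np.argsort(-counts, kind="stable")
    ranks = np.empty(vocab.size, dtype=np.int64)
    ranks[order] = np.arange(1, vocab.size + 1)
    return ranks


def rank_table(words1: WordSequence, words2: WordSequence) -> WordRankTable:
    """Joint vocabulary with per-sequence probabilities, ranks and weights."""
    if words1.word_length != words2.word_length:
        raise ValueError("word sequences must share the same word length m")
    w1, w2 = words1.words, words2.words
    if w1.size == 0 or w2.size == 0:
        raise InsufficientDataError("empty word sequence in rank table")
    vocab = np.union1d(w1, w2)
    c1 = _counts_over(vocab, w1)
    c2 = _counts_over(vocab, w2)
    p1 = c1 / w1.size
    p2 = c2 / w2.size
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = np.where(p1 > 0, -p1 * np.log(np.where(p1 > 0, p1, 1.0)), 0.0)
        h2 = np.where(p2 > 0, -p2 * np.log(np.where(p2 > 0, p2, 1.0)), 0.0)
    total = (h1 + h2).sum()
    if total > 0:
        weights = (h1 + h2) / total
    else:
        # both sequences constant: every Shannon term vanishes; fall back to
        # uniform weights so the distribution invariant holds
        weights = np.full(vocab.size, 1.0 / vocab.size)
    return WordRankTable(
        vocabulary=vocab, p1=p1, p2=p2,
        k1=_ranks(vocab, c1), k2=_ranks(vocab, c2),
        weights=weights,
    )


def ibs_distance(table: WordRankTable) -> float:
    """Entropy-weighted mean rank displacement; in [0, (L-1)/L], symmetric."""
    L = table.n_words
    return float(
        np.sum(np.abs(table.k1 - table.k2) * table.weights) / L
    )


def _segment_words(
    segment: np.ndarray, m: int, s: int, tie_symbol: Literal[0, 1]
) -> WordSequence | None:
    """Full per-segment chain; None when the segment is too short."""
    try:
        coarse = coarse_grain(segment, s)
        bits = symbolize(coarse, tie_symbol=tie_symbol)
        return make_words(bits, m)
    except (ValueError, InsufficientDataError):
        return None


def ibs_series(
    segments: SegmentSet,
    m: int = DEFAULT_WORD_LENGTH,
    s: int = DEFAULT_SCALE,
    *,
    tie_symbol: Literal[0, 1] = 0,
) -> IBSSeries:
    """IBS distance for every adjacent segment pair of a record.

    Pairs where either segment yields an empty word sequence are skipped with
    a log entry; fewer than two usable segments is an error.
    """
    if len(segments) < 2:
        raise InsufficientDataError(
            f"{segments.record_id}: need >= 2 segments for an IBS series, "
            f"got {len(segments)}"
        )
    word_seqs = [
        _segment_words(np.asarray(seg, dtype=float), m, s, tie_symbol)
        for seg in segments
    ]
    values: list[float] = []
    for k in range(len(word_seqs) - 1):
        a, b = word_seqs[k], word_seqs[k + 1]
        if a is None or b is None:
            logger.info(
                "%s: pair (%d, %d) skipped (segment too short for m=%d, s=%d)",
                segments.record_id, k, k + 1, m, s,
            )
            continue
        values.append(ibs_distance(rank_table(a, b)))
    if not values:
        raise InsufficientDataError(
            f"{segments.record_id}: no usable adjacent segment pair at m={m}, s={s}"
        )
    return IBSSeries(record_id=segments.record_id, values=np.asarray(values))


def ibs_index(series: IBSSeries) -> float:
    """Record-level IBS index: mean of the adjacent-pair distances."""
    if series.n_values == 0:
        return float("nan")
    return float(series.values.mean())
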