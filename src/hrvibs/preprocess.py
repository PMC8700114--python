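"""Record cleaning and non-overlapping 1-minute segmentation.

Cleaning drops the first and the last interval of a record (edge beats of a
24-h Holter extraction are unreliable) and removes intervals longer than 3 s
(singular-value interference).  Short intervals are deliberately retained:
normal subjects tend to have *longer* RR intervals than CHF patients, so a
lower-bound filter would bias the comparison.

Segmentation walks the cleaned record greedily, accumulating interval
durations and closing a segment when adding the next beat would exceed the
segment length; this needs no absolute timestamps.  A ``wallclock`` mode that
bins beats by fixed wall-clock windows is available for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_rr import InsufficientDataError, RRSeries

__all__ = ["SegmentSet", "clean_rr", "segment_minutes", "DEFAULT_MAX_RR"]

logger = logging.getLogger(__name__)

DEFAULT_MAX_RR = 3.0  # seconds; upper outlier threshold
DEFAULT_SEGMENT_LENGTH = 60.0
DEFAULT_MIN_BEATS = 10  # word construction at m=2,s=2 needs >= 6 beats; PSD more


@dataclass(frozen=True)
class SegmentSet:
    """Ordered, contiguous, non-overlapping RR segments from one record."""

    record_id: str
    segments: tuple[np.ndarray, ...]
    segment_length: float = DEFAULT_SEGMENT_LENGTH

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def clean_rr(series: RRSeries, max_rr: float = DEFAULT_MAX_RR) -> RRSeries:
    """Trim the end beats (first pass only) and drop intervals > ``max_rr``.

    End-trimming runs once per record, tracked by the ``cleaned`` flag, so
    re-applying the function to its own output only repeats the (idempotent)
    upper-outlier filter.
    """
    iv = series.intervals
    if not series.cleaned:
        if iv.size < 3:
            raise InsufficientDataError(
                f"{series.record_id}: need >= 3 intervals to clean, got {iv.size}"
            )
        iv = iv[1:-1]
    kept = iv[iv <= max_rr]
    n_dropped = iv.size - kept.size
    if n_dropped:
        logger.info(
            "%s: dropped %d interval(s) > %.3g s", series.record_id, n_dropped, max_rr
        )
    return series.with_intervals(kept, cleaned=True)


def _greedy_segments(
    iv: np.ndarray, segment_length: float
) -> list[np.ndarray]:
    """Greedy fill: close a segment when the next beat would overflow it."""
    segments: list[np.ndarray] = []
    start = 0
    acc = 0.0
    for i, r in enumerate(iv):
        if acc + r > segment_length:
            segments.append(iv[start:i])
            start = i
            acc = 0.0
        acc += r
    # trailing partial segment (never closed by overflow) is discarded
    return segments


def _wallclock_segments(
    iv: np.ndarray, segment_length: float
) -> list[np.ndarray]:
    """Bin beats by the wall-clock window containing each beat's end time."""
    ends = np.cumsum(iv)
    # a beat ending exactly on a boundary belongs to the window it closes
    bins = np.ceil(ends / segment_length).astype(int) - 1
    n_complete = int(ends[-1] // segment_length)  # last partial window dropped
    return [iv[bins == b] for b in range(n_complete)]


def segment_minutes(
    series: RRSeries,
    segment_length: float = DEFAULT_SEGMENT_LENGTH,
    min_beats: int = DEFAULT_MIN_BEATS,
    *,
    bin_mode: Literal["duration", "wallclock"] = "duration",
) -> SegmentSet:
    """Split a cleaned record into non-overlapping ~1-minute segments.

    Segments with fewer than ``min_beats`` beats are discarded (logged); a
    record yielding zero complete segments raises
    :class:`~hrvibs.io_rr.InsufficientDataError`.
    """
    iv = np.asarray(series.intervals, dtype=float)
    if bin_mode == "duration":
        raw = _greedy_segments(iv, segment_length)
    elif bin_mode == "wallclock":
        raw = _wallclock_segments(iv, segment_length)
    else:
        raise ValueError(f"unknown bin_mode {bin_mode!r}")
    kept: list[np.ndarray] = []
    for k, seg in enumerate(raw):
        if seg.size < min_beats:
            logger.info(
                "%s: segment %d discarded (%d < %d beats)",
                series.record_id, k, seg.size, min_beats,
            )
            continue
        kept.append(seg)
    if not kept:
        raise InsufficientDataError(
            f"{series.record_id}: no complete {segment_length:g}-s segment "
            f"with >= {min_beats} beats"
        )
    return SegmentSet(
        record_id=series.record_id,
        segments=tuple(kept),
        segment_length=segment_length,
    )
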