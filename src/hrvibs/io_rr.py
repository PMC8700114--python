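"""Reading and writing RR-interval series and per-record index tables.

The canonical on-disk form for an RR series is a plain-text file with one
interval per line (seconds or milliseconds), blank lines ignored and ``#``
comment lines allowed.  WFDB annotation files (the PhysioNet beat-annotation
format) are supported through the optional :mod:`wfdb` package.

All intervals are stored internally in **seconds**; millisecond input is
converted on read.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "RRSeries",
    "IndexRecord",
    "RRParseError",
    "InsufficientDataError",
    "read_rr_text",
    "write_rr_text",
    "read_wfdb_intervals",
    "write_indices_csv",
    "read_indices_csv",
]

# Beat annotation codes of the WFDB standard (symbols that mark QRS complexes,
# normal or ectopic); anything else (rhythm changes, noise, comments) never
# produces an RR interval.
WFDB_BEAT_SYMBOLS = frozenset(
    "NLRBAaJSVrFejnE/fQ?"
)

#: Median token above this value means the file is in milliseconds.  A
#: physiologic RR interval is < 3 s and > 300 ms, so 10 separates the scales
#: with two orders of magnitude of slack on either side.
MS_INFERENCE_MEDIAN = 10.0


class RRParseError(ValueError):
    """A text RR file contained a token that is not a number."""


class InsufficientDataError(ValueError):
    """An operation received fewer beats/segments/values than it needs."""


@dataclass(frozen=True)
class RRSeries:
    """A labelled sequence of beat-to-beat intervals.

    Parameters
    ----------
    record_id:
        Identifier for the recording (file stem, PhysioNet record name, ...).
    intervals:
        Beat-ordered RR intervals in seconds; all strictly positive.
    group:
        ``"normal"``, ``"chf"`` or ``"unknown"``.
    source:
        ``"text"``, ``"wfdb"`` or ``"synthetic"``.
    cleaned:
        True once the end-trimming pass of the preprocessor has run; the
        >3 s outlier filter alone does not set it.
    """

    record_id: str
    intervals: np.ndarray
    group: Literal["normal", "chf", "unknown"] = "unknown"
    source: Literal["text", "wfdb", "synthetic"] = "text"
    cleaned: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if arr.size and not np.all(arr > 0):
            raise ValueError(f"record {self.record_id!r}: all intervals must be > 0")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration(self) -> float:
        """Total duration in seconds (sum of intervals)."""
        return float(self.intervals.sum())

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative beat times in seconds, monotonically increasing."""
        return np.cumsum(self.intervals)

    def with_intervals(self, intervals: np.ndarray, *, cleaned: bool | None = None) -> "RRSeries":
        return replace(
            self,
            intervals=np.asarray(intervals, dtype=float),
            cleaned=self.cleaned if cleaned is None else cleaned,
        )


@dataclass
class IndexRecord:
    """Per-record feature triple used by the screening layer.

    A value of ``nan`` marks an index that could not be computed for the
    record (the explicit missing marker).
    """

    record_id: str
    group: Literal["normal", "chf", "unknown"]
    lf_hf: float = math.nan
    ibs: float = math.nan
    fapen_ibs: float = math.nan

    _FIELDS = ("lf_hf", "ibs", "fapen_ibs")

    def feature(self, name: str) -> float:
        if name not in self._FIELDS:
            raise KeyError(f"unknown index {name!r}; expected one of {self._FIELDS}")
        return getattr(self, name)


def _iter_tokens(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped


def read_rr_text(
    path: str | Path,
    units: Literal["s", "ms", "auto"] = "auto",
    *,
    record_id: str | None = None,
    group: Literal["normal", "chf", "unknown"] = "unknown",
) -> RRSeries:
    """Read a one-interval-per-line RR text file.

    ``units="auto"`` infers milliseconds when the median token exceeds
    ``MS_INFERENCE_MEDIAN`` (physiologic RR is < 3 in seconds, > 300 in ms).

    Raises
    ------
    RRParseError
        On a non-numeric token, naming the offending line number.
    InsufficientDataError
        If the file holds no intervals at all.
    """
    path = Path(path)
    values: list[float] = []
    for lineno, token in _iter_tokens(path):
        try:
            values.append(float(token))
        except ValueError:
            raise RRParseError(
                f"{path}: line {lineno}: not a number: {token!r}"
            ) from None
    if not values:
        raise InsufficientDataError(f"{path}: no RR intervals found (empty file)")
    arr = np.asarray(values, dtype=float)
    if units == "auto":
        units = "ms" if float(np.median(arr)) > MS_INFERENCE_MEDIAN else "s"
    if units == "ms":
        arr = arr / 1000.0
    elif units != "s":
        raise ValueError(f"unknown units {units!r}")
    return RRSeries(
        record_id=record_id if record_id is not None else path.stem,
        intervals=arr,
        group=group,
        source="text",
    )


def write_rr_text(series: RRSeries, path: str | Path) -> None:
    """Write an RR series as one interval per line, seconds, full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        for v in series.intervals:
            fh.write(repr(float(v)) + "\n")


def _annotation_to_series(
    sample: np.ndarray,
    symbol: Sequence[str],
    fs: float,
    record_id: str,
    beats_only: bool,
) -> RRSeries:
    sample = np.asarray(sample, dtype=float)
    symbol = list(symbol)
    if beats_only:
        keep = np.fromiter(
            (s in WFDB_BEAT_SYMBOLS for s in symbol), dtype=bool, count=len(symbol)
        )
        sample = sample[keep]
    times = sample / float(fs)
    if times.size < 2:
        raise InsufficientDataError(
            f"{record_id}: fewer than two beat annotations; no intervals"
        )
    return RRSeries(
        record_id=record_id,
        intervals=np.diff(times),
        source="wfdb",
    )


def read_wfdb_intervals(
    record_path: str | Path,
    extension: str = "atr",
    *,
    beats_only: bool = True,
) -> RRSeries:
    """Read RR intervals from a WFDB annotation file (PhysioNet format).

    Intervals are successive differences of beat-annotation times in seconds.
    ``beats_only`` keeps only annotations whose symbol is a conventional beat
    label; non-beat events (rhythm changes, artifacts) never produce
    intervals.  The toggle exists because published RR databases do not
    always state whether non-normal beats were excluded upstream.

    Requires the optional :mod:`wfdb` package.
    """
    try:
        import wfdb  # noqa: PLC0415 - optional dependency
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "reading WFDB annotations requires the optional 'wfdb' package "
            "(pip install hrvibs[wfdb])"
        ) from exc
    record_path = Path(record_path)
    try:
        ann = wfdb.rdann(str(record_path), extension)
    except Exception as exc:  # pragma: no cover - passthrough format errors
        raise ValueError(f"{record_path}: cannot read WFDB annotation: {exc}") from exc
    fs = ann.fs if ann.fs else 1.0
    return _annotation_to_series(
        ann.sample, ann.symbol, fs, record_path.name, beats_only
    )


_CSV_HEADER = ["record_id", "group", "lf_hf", "ibs", "fapen_ibs"]


def write_indices_csv(records: Sequence[IndexRecord], path: str | Path) -> None:
    """Write the per-record index table (header + one row per record).

    Values are written with 10 significant digits so a write/read round-trip
    is lossless to well below 1e-9.
    """
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for rec in records:
            writer.writerow(
                [rec.record_id, rec.group]
                + [f"{getattr(rec, f):.10g}" for f in IndexRecord._FIELDS]
            )


def read_indices_csv(path: str | Path) -> list[IndexRecord]:
    """Read back a table written by :func:`write_indices_csv`."""
    out: list[IndexRecord] = []
    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_HEADER:
            raise ValueError(f"{path}: unexpected header {reader.fieldnames}")
        for row in reader:
            out.append(
                IndexRecord(
                    record_id=row["record_id"],
                    group=row["group"],  # type: ignore[arg-type]
                    lf_hf=float(row["lf_hf"]),
                    ibs=float(row["ibs"]),
                    fapen_ibs=float(row["fapen_ibs"]),
                )
            )
    return out
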