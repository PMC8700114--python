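"""Fuzzy approximate entropy (fApEn) of the per-record IBS series.

The IBS series u(1..N) is embedded in M dimensions with each window's own
mean removed,

    X_i = (u(i), ..., u(i+M-1)) - mean(u(i..i+M-1)),   i = 1..N-M+1,

vector distances are Chebyshev (maximum absolute componentwise difference),
and similarity is graded by a Gaussian fuzzy membership
FZ(d, r) = exp(-(d/r)^2) instead of a hard threshold.  fApEn is the
log-likelihood drop when the embedding dimension grows by one:

    fApEn(M, r, N) = Phi^M(r) - Phi^(M+1)(r).

Two summation conventions are provided.  ``"printed"`` (the default) keeps
the self-match j = i and uses N-M+1 denominators with the j-sum running to
N-M; ``"standard"`` excludes the self-match with N-M-1 denominators, the
conventional fuzzy-entropy estimator.  For a constant series the printed
form gives exactly ln((N-M)/(N-M+1)) - ln((N-M-1)/(N-M)) and the standard
form gives 0.

The tolerance r defaults to 0.25 times the series SD (``relative_sd``
mode), which makes the index invariant to a rescaling of u; ``absolute``
mode uses r as given.  Applied to the IBS series of a 24-h record the result
is the fApEn_IBS index: low values mean the minute-to-minute similarity
pattern itself is regular — the CHF signature — so CHF records score lower
fApEn_IBS than normal ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .io_rr import InsufficientDataError, RRSeries
from .preprocess import clean_rr, segment_minutes
from .ibs import DEFAULT_SCALE, DEFAULT_WORD_LENGTH, IBSSeries, ibs_series

__all__ = [
    "FapenConfig", "EmbeddingSet", "embed", "similarity_degree",
    "phi", "fapen", "fapen_ibs",
]

FormulaMode = Literal["printed", "standard"]
ToleranceMode = Literal["relative_sd", "absolute"]


@dataclass(frozen=True)
class FapenConfig:
    """Parameters of the fApEn estimator.

    embed_dim:
        Embedding dimension M (>= 1); 2 by default.
    tolerance_factor:
        r; multiplied by the series SD in ``relative_sd`` mode, used as-is in
        ``absolute`` mode.  0.25 by default.
    formula_mode:
        Summation convention, see module docstring.
    """

    embed_dim: int = 2
    tolerance_factor: float = 0.25
    tolerance_mode: ToleranceMode = "relative_sd"
    formula_mode: FormulaMode = "printed"

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError(f"embed_dim must be >= 1, got {self.embed_dim}")
        if self.tolerance_factor <= 0:
            raise ValueError(
                f"tolerance_factor must be > 0, got {self.tolerance_factor}"
            )


@dataclass(frozen=True)
class EmbeddingSet:
    """Baseline-removed embedding vectors of a series."""

    vectors: np.ndarray   # (N - m + 1, m), each row sums to 0
    baselines: np.ndarray  # window means u0(i)


def embed(u: np.ndarray, m: int) -> EmbeddingSet:
    """Windows of width ``m`` with each window's own mean subtracted."""
    u = np.asarray(u, dtype=float)
    if u.size < m + 1:
        raise InsufficientDataError(
            f"series of length {u.size} too short to embed at m={m}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(u, m)
    baselines = windows.mean(axis=1)
    return EmbeddingSet(
        vectors=windows - baselines[:, None], baselines=baselines
    )


def similarity_degree(d: float | np.ndarray, r: float) -> float | np.ndarray:
    """Gaussian fuzzy membership exp(-(d/r)^2); 1 at d=0, strictly decreasing."""
    if r <= 0:
        raise ValueError(f"tolerance r must be > 0, got {r}")
    return np.exp(-np.square(np.asarray(d, dtype=float) / r))


def _membership_matrix(u: np.ndarray, m: int, r: float) -> np.ndarray:
    vectors = embed(u, m).vectors
    if m == 1:
        d = np.abs(vectors - vectors.T)  # (n,1) vs (1,n) broadcast
    else:
        d = cdist(vectors, vectors, metric="chebyshev")
    return similarity_degree(d, r)


def phi(
    u: np.ndarray, m: int, r: float, mode: FormulaMode = "printed"
) -> float:
    """Mean log match possibility Phi^m(r) under either summation convention."""
    u = np.asarray(u, dtype=float)
    N = u.size
    D = _membership_matrix(u, m, r)  # (N-m+1) x (N-m+1)
    if mode == "printed":
        # phi_i = sum_{j=1..N-m} D_ij / (N-m+1), i = 1..N-m+1 (self kept)
        phis = D[:, : N - m].sum(axis=1) / (N - m + 1)
        return float(np.log(phis).mean())
    if mode == "standard":
        # self-match excluded; i, j = 1..N-m with (N-m-1) denominators
        if N - m - 1 < 1:
            raise InsufficientDataError(
                f"standard-mode phi needs N >= m+2 non-self pairs (N={N}, m={m})"
            )
        sub = D[: N - m, : N - m].copy()
        np.fill_diagonal(sub, 0.0)  # summing tiny memberships then subtracting
        phis = sub.sum(axis=1) / (N - m - 1)  # the self 1.0 would cancel badly
        return float(np.log(phis).mean())
    raise ValueError(f"unknown formula mode {mode!r}")


def _effective_tolerance(u: np.ndarray, config: FapenConfig) -> float:
    if config.tolerance_mode == "absolute":
        return config.tolerance_factor
    if config.tolerance_mode != "relative_sd":
        raise ValueError(f"unknown tolerance mode {config.tolerance_mode!r}")
    sd = float(np.std(u))  # population SD
    if sd == 0.0:
        warnings.warn(
            "constant series: SD is zero; falling back to absolute tolerance",
            RuntimeWarning,
            stacklevel=3,
        )
        return config.tolerance_factor
    return config.tolerance_factor * sd


def fapen(u: np.ndarray, config: FapenConfig = FapenConfig()) -> float:
    """fApEn(M, r, N) = Phi^M(r) - Phi^(M+1)(r) of a series."""
    u = np.asarray(u, dtype=float)
    M = config.embed_dim
    if u.size < M + 2:
        raise InsufficientDataError(
            f"series of length {u.size} too short for fApEn at M={M} (need M+2)"
        )
    r_eff = _effective_tolerance(u, config)
    return (
        phi(u, M, r_eff, config.formula_mode)
        - phi(u, M + 1, r_eff, config.formula_mode)
    )


def fapen_ibs(
    record: RRSeries,
    m_word: int = DEFAULT_WORD_LENGTH,
    s: int = DEFAULT_SCALE,
    config: FapenConfig = FapenConfig(),
    *,
    segment_length: float = 60.0,
    min_beats: int = 10,
    bin_mode: Literal["duration", "wallclock"] = "duration",
    precomputed_ibs: IBSSeries | None = None,
) -> float:
    """Full chain: clean -> segment -> IBS series -> fApEn of the IBS values.

    ``precomputed_ibs`` short-circuits the chain when the IBS series has
    already been computed (e.g. inside the pipeline); insufficient-data
    errors from any stage propagate with the stage named in the message.
    """
    if precomputed_ibs is None:
        cleaned = clean_rr(record)
        segments = segment_minutes(
            cleaned, segment_length, min_beats, bin_mode=bin_mode
        )
        series = ibs_series(segments, m=m_word, s=s)
    else:
        series = precomputed_ibs
    return fapen(series.values, config)
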