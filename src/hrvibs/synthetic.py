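"""Synthetic 24-h RR-interval generator.

Every downstream stage (segmentation, LF/HF, IBS, fApEn, screening) is
testable without downloading Holter databases by generating RR series with
controllable spectral content and fluctuation-pattern regularity:

    r_i = mean_rr + lf_amp * sin(2*pi*0.1*t_i) + hf_amp * sin(2*pi*0.3*t_i) + eps_i

with ``t_i`` the cumulative beat time (so the modulation lives at real-time
frequencies inside the standard LF / HF bands) and ``eps_i`` white Gaussian
jitter.  A ``periodic`` pattern-repeat mode replays the same modulation
phase — including the jitter sequence — every ``repeat_minutes``, forcing
near-identical fluctuation patterns in successive minutes the way a
low-variability, rhythmically regular recording does.

The cohort generator emulates the two study arms: "normal-like" records have
sympathovagal balance tilted to LF (LF/HF > 2 in expectation), larger
beat-to-beat variability and no pattern repetition; "CHF-like" records have
LF/HF < 1.5, smaller jitter and a periodic fluctuation pattern, so a cohort
reproduces the expected ordering (normal above CHF) of LF/HF, IBS and
fApEn_IBS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io_rr import RRSeries

__all__ = ["SyntheticProfile", "generate_rr_series", "generate_cohort",
           "NORMAL_PROFILE_KWARGS", "CHF_PROFILE_KWARGS"]

LF_TONE_HZ = 0.1  # center of the 0.04-0.15 Hz LF band
HF_TONE_HZ = 0.3  # inside the 0.15-0.4 Hz HF band


@dataclass(frozen=True)
class SyntheticProfile:
    """Parameters of one synthetic record; all amplitudes in seconds.

    ``mean_rr - (lf_amp + hf_amp + 4*noise_sd)`` must stay positive so no
    non-positive interval can be produced (jitter is clipped at 4 SD).
    """

    mean_rr: float = 0.8
    lf_amp: float = 0.04
    hf_amp: float = 0.012
    noise_sd: float = 0.03
    pattern_repeat: Literal["none", "periodic"] = "none"
    repeat_minutes: float = 3.0
    duration: float = 86400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr - (self.lf_amp + self.hf_amp + 4.0 * self.noise_sd) <= 0:
            raise ValueError(
                "profile can produce non-positive intervals: require "
                "mean_rr - (lf_amp + hf_amp + 4*noise_sd) > 0"
            )
        if self.duration <= 0 or self.repeat_minutes <= 0:
            raise ValueError("duration and repeat_minutes must be positive")
        if self.pattern_repeat not in ("none", "periodic"):
            raise ValueError(f"unknown pattern_repeat {self.pattern_repeat!r}")


# Cohort arm calibrations.  The LF/HF tone amplitudes are set so the expected
# band-power ratio (tone power amp^2/2 plus the white-jitter floor spread over
# the resampled bandwidth) lands above 2 for the normal arm and below 1.5 for
# the CHF arm; the CHF repeat period of 3 min is an integer number of cycles
# of both 0.1 Hz and 0.3 Hz, so replaying the modulation phase is
# phase-continuous and only the jitter pattern repeats.
NORMAL_PROFILE_KWARGS = dict(
    mean_rr=0.8, lf_amp=0.04, hf_amp=0.012, noise_sd=0.03, pattern_repeat="none"
)
CHF_PROFILE_KWARGS = dict(
    mean_rr=0.6, lf_amp=0.01, hf_amp=0.015, noise_sd=0.01,
    pattern_repeat="periodic", repeat_minutes=3.0,
)


def generate_rr_series(
    profile: SyntheticProfile,
    *,
    record_id: str | None = None,
    group: Literal["normal", "chf", "unknown"] = "unknown",
) -> RRSeries:
    """Generate one RR series from a profile; fixed seed gives identical output.

    Beats are emitted until the cumulative duration reaches
    ``profile.duration`` (so the total is within one beat of the request).
    """
    rng = np.random.default_rng(profile.seed)
    n_est = int(profile.duration / profile.mean_rr) + 64
    period_s = profile.repeat_minutes * 60.0
    periodic = profile.pattern_repeat == "periodic"

    # Pre-draw jitter; in periodic mode one period's worth of beats is drawn
    # and replayed so successive periods carry the same fluctuation pattern.
    if periodic:
        n_per_period = max(int(math.ceil(period_s / profile.mean_rr)) + 8, 1)
        base_noise = rng.standard_normal(n_per_period)
    else:
        base_noise = rng.standard_normal(n_est)

    intervals = np.empty(n_est)
    t = 0.0
    i = 0
    while t < profile.duration:
        if i >= intervals.size:
            intervals = np.concatenate([intervals, np.empty(n_est)])
            if not periodic:
                base_noise = np.concatenate(
                    [base_noise, rng.standard_normal(n_est)]
                )
        if periodic:
            phase_t = math.fmod(t, period_s)
            beat_in_period = int(phase_t / profile.mean_rr) % base_noise.size
            eps = base_noise[beat_in_period]
        else:
            phase_t = t
            eps = base_noise[i]
        eps = min(max(eps, -4.0), 4.0) * profile.noise_sd
        r = (
            profile.mean_rr
            + profile.lf_amp * math.sin(2.0 * math.pi * LF_TONE_HZ * phase_t)
            + profile.hf_amp * math.sin(2.0 * math.pi * HF_TONE_HZ * phase_t)
            + eps
        )
        intervals[i] = r
        t += r
        i += 1
    rid = record_id if record_id is not None else f"synthetic-{profile.seed}"
    return RRSeries(
        record_id=rid, intervals=intervals[:i], group=group, source="synthetic"
    )


def generate_cohort(
    n_normal: int,
    n_chf: int,
    seed: int,
    *,
    duration: float = 86400.0,
) -> list[RRSeries]:
    """Generate a labelled two-arm cohort; deterministic in ``seed``.

    Per-record seeds are derived from the cohort seed via
    ``numpy.random.SeedSequence`` so records are mutually independent yet the
    cohort is reproducible bit-for-bit.
    """
    if n_normal < 0 or n_chf < 0:
        raise ValueError("cohort counts must be >= 0")
    n_total = n_normal + n_chf
    if n_total == 0:
        return []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_total) % (2**31)
    cohort: list[RRSeries] = []
    for k in range(n_normal):
        profile = SyntheticProfile(
            **NORMAL_PROFILE_KWARGS, duration=duration, seed=int(child_seeds[k])
        )
        cohort.append(
            generate_rr_series(profile, record_id=f"normal-{k:03d}", group="normal")
        )
    for k in range(n_chf):
        profile = SyntheticProfile(
            **CHF_PROFILE_KWARGS,
            duration=duration,
            seed=int(child_seeds[n_normal + k]),
        )
        cohort.append(
            generate_rr_series(profile, record_id=f"chf-{k:03d}", group="chf")
        )
    return cohort
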