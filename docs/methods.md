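# Methods

## Model and pipeline

A 24-h RR-interval record is treated as a sequence of strictly positive
beat-to-beat durations in seconds. The analysis assumes the record is long
enough to yield many 1-minute segments and that the fluctuation *pattern*
(the order of accelerations and decelerations), not the absolute interval
values, carries the diagnostic signal. The chain is:

1. **Cleaning** — drop the first and last interval of the record and every
   interval > 3 s. No lower bound is applied: short intervals are
   physiologic in CHF, and removing them would bias the group contrast.
   End-trimming runs once per record (tracked by a `cleaned` flag); the
   upper-outlier filter is idempotent.
2. **Segmentation** — greedy fill by cumulative duration: a segment closes
   when adding the next beat would exceed 60 s; the trailing partial
   segment is discarded, as are segments with fewer than `min_beats = 10`
   beats (word construction at m = 2, s = 2 needs ≥ 6 beats and the
   spectral estimate more). Greedy fill needs no absolute timestamps; a
   `wallclock` mode (fixed 60-s windows, a beat belonging to the window
   containing its end time, boundary beats closing their window) exists for
   sensitivity analysis because the segment-closure convention is a
   genuinely open choice.
3. **LF/HF** — per segment, cubic-spline resampling of the tachogram at
   4 Hz (standard HRV practice for uneven sampling), mean removal, boxcar
   FFT periodogram, trapezoidal band powers over half-open bands
   [0.04, 0.15) and [0.15, 0.4) Hz so 0.15 Hz is counted exactly once.
   Per-record value: mean of per-segment ratios over segments with nonzero
   HF power (`ratio-of-means` available as an alternative aggregation).
   No taper: a 1-min segment gives ~0.017 Hz resolution, fine for bands
   0.11 and 0.25 Hz wide.
4. **IBS** — per adjacent segment pair: coarse-grain (scale s block means,
   remainder dropped), symbolise (rise → 1, fall → 0, tie → 0 by default —
   the deterministic completion of a rise/fall rule; configurable),
   sliding m-bit words read big-endian, joint-vocabulary rank table,
   entropy-weighted rank distance D. Ranks order by descending frequency
   with ties broken by ascending word code (deterministic and symmetric);
   words absent from one sequence get probability 0 and rank at the bottom
   under the same tie-break, sequentially. Weights are the per-word Shannon
   terms −p₁log p₁ − p₂log p₂ normalised by their sum so they form a
   distribution (natural log; the base cancels). When both sequences are
   constant every Shannon term vanishes and weights fall back to uniform
   1/L — D is rank-driven there, so the choice only preserves the Σw = 1
   invariant. The distance divides by L (an L−1 variant exists in the
   literature; the divisor only rescales and is not exposed as a default).
5. **fApEn_IBS** — fuzzy approximate entropy of the IBS series with
   embedding M = 2, Gaussian membership exp(−(d/r)²), tolerance
   r = 0.25 × population SD of the series (`relative_sd`), Chebyshev vector
   distances, each embedding window reduced by its own mean. A constant
   series has SD 0; the tolerance then falls back to the absolute value
   with a warning rather than failing.

## The two fApEn summation conventions

`formula_mode="printed"` (default) keeps the self-match j = i and uses
N−m+1 denominators with the inner sum over j = 1..N−m and the outer mean
over i = 1..N−m+1. `formula_mode="standard"` is the conventional
self-excluded estimator (denominators N−m−1, i and j over 1..N−m). The two
differ systematically: the self-match form is bounded away from the true
entropy at small tolerance (as r → 0 every φᵢ approaches the same constant,
so the estimate collapses instead of growing), which is why the
monotone-in-r property is a theorem only for the standard form and is
tested there. Constant-series closed forms: printed,
ln((N−m)/(N−m+1)) − ln((N−m−1)/(N−m)); standard, exactly 0. The standard
mode zeroes the membership-matrix diagonal before summing rather than
subtracting 1 afterwards; the subtraction cancels catastrophically when the
off-diagonal memberships are ~e⁻²⁰.

The Gaussian membership is exp(−(d/r)²); the common alternative
exp(−d²/(2r²)) is the same function at a rescaled r, so the tolerance grid
absorbs it.

## Screening

CHF is the positive class. The single-index Fisher screen is the 1-D linear
discriminant with equal priors and pooled variance, whose boundary reduces
to the midpoint of the group means; it is evaluated in-sample (the
cross-validation protocol applies only to the multi-feature classifiers)
and its decisions are invariant under positive affine transforms of the
feature. Cross-validation is stratified 5-fold with shuffling seeded by the
run seed; `folds = n` falls back to leave-one-out, where stratification is
vacuous. Classifiers: KNN with k = 5; random forest with 100 trees seeded
from the run seed; SVM with polynomial kernel of degree 3 and default
regularisation (tree count and SVM hyperparameters are conventional
defaults — they shape the multi-feature numbers, which are
data-dependent and not asserted anywhere). ROC curves pool held-out scores
(class probabilities, or decision values for the SVM) across folds; AUC is
the Mann–Whitney statistic with rank-midpoint ties. Group contrasts use
Welch's t-test by default (`equal_var=True` restores Student's form).

The parameter sweep recomputes the IBS series and fApEn_IBS for every
(m, s) in 2..6 × 1..7 — cleaning and segmentation are (m, s)-independent
and run once per record — and stores the Fisher-screen accuracy of
fApEn_IBS per cell; cells where every record fails are marked missing
rather than fatal.

## Synthetic data

The generator emulates the two study arms with an additive model:
r_i = mean_rr + lf_amp·sin(2π·0.1·t_i) + hf_amp·sin(2π·0.3·t_i) + ε_i, with
t_i the cumulative beat time (so the tones live at real-time frequencies
squarely inside the LF and HF bands) and ε_i white Gaussian jitter clipped
at 4 SD so intervals stay positive by construction. The `periodic` mode
replays the modulation phase — including the jitter pattern — every
`repeat_minutes`, forcing near-identical fluctuation patterns across
periods.

Arm calibrations (chosen once, from the band-power arithmetic of the
additive model): normal-like — mean RR 0.8 s, lf_amp 0.04 s, hf_amp
0.012 s, noise SD 0.03 s, no repetition, giving expected LF/HF > 2 and
jitter-dominated symbol patterns; CHF-like — mean RR 0.6 s (CHF runs a
faster heart rate), lf_amp 0.01 s, hf_amp 0.015 s, noise SD 0.01 s and a
3-min pattern repeat, giving LF/HF < 1.5 and tone-dominated, repeating
patterns. The 3-min period is an integer number of cycles of both 0.1 Hz
and 0.3 Hz, so phase replay is continuous and does not smear the spectral
tones. Per-record seeds derive from the cohort seed via
`numpy.random.SeedSequence`, making cohorts bit-reproducible.

What the generator does *not* emulate: integral-pulse-frequency-modulation
dynamics, baroreflex feedback, circadian drift, ectopy and artifacts beyond
white jitter, and the age/sex/drug heterogeneity of clinical cohorts. The
synthetic arms are far better separated than clinical groups, so passing
directionality and accuracy checks on them demonstrates that the chain
measures what it claims in the directions it claims — not that clinical
screening accuracy would reach the same numbers.

## Numerical choices and degenerate inputs

- Internal unit is seconds everywhere; text readers auto-detect
  milliseconds via median token > 10 (physiologic RR is < 3 s, > 300 ms).
- Word encoding is big-endian; the distance is invariant to any relabelling
  of word codes, so this is fixed purely for reproducibility.
- Population (not sample) SD for the fApEn tolerance; the difference is
  negligible at the series lengths involved but must be pinned for exact
  oracle comparison.
- Index values that cannot be computed (too few beats/segments/IBS values)
  are explicit NaN markers; records missing an index are excluded from the
  affected analysis and logged, never silently imputed.
- The index CSV writes 10 significant digits, round-tripping below 1e-9.

## Problem sizes

The test suite exercises the full chain on 30-min to 2-h synthetic records
and one 20/20 cohort of 24-h records; the acceptance script uses the 20/20
24-h cohort for the indices and screens and a 10/10 cohort of 3-h records
for the 35-cell parameter sweep. These sizes are the package's own choices:
the 24-h cohort matches the intended recording length, and the sweep cohort
is sized so the 35-fold recomputation of the full similarity chain stays
proportionate to what it demonstrates (grid shape and the reference cell).

## Known limitations

- The printed-form fApEn estimator is kept as the default for fidelity to
  the published description even though the standard form has better
  estimator properties; both are exposed and oracle-tested.
- Reading WFDB annotation files requires the optional `wfdb` dependency;
  the annotation-to-interval contract is tested against stub annotation
  content so the logic is covered without it.
- LF/HF on 1-min segments is below the 5-min convention for spectral HRV;
  the short window is a deliberate real-time design and the band resolution
  argument above is the justification, but absolute LF/HF values are not
  comparable to 5-min-window literature values.
- In-sample Fisher screening overstates generalisation by design (it
  mirrors a single-pass discriminant protocol); the cross-validated
  classifiers are the generalisation estimates.
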