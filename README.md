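# hrvibs

Similarity-change analysis of heart-rate variability (HRV) for congestive
heart failure (CHF) screening.

CHF degrades autonomic regulation of the heart, and the fluctuation pattern
of beat-to-beat (RR) intervals carries its signature: CHF patients show
minute-to-minute heart-rate fluctuation patterns that are *more similar to
each other* and *less complex over the day* than those of healthy subjects.
`hrvibs` quantifies this from 24-h RR-interval recordings with three
per-record indices and a screening layer on top, for physiologists and
biomedical engineers working with Holter-derived RR series (e.g. the
PhysioNet normal-sinus-rhythm and CHF RR-interval databases).

## The method

Each record is cleaned (first/last beat dropped, intervals > 3 s removed —
no lower-bound filter, since healthy RR tends to be longer than CHF RR) and
split into non-overlapping 1-minute segments. Then:

**LF/HF** — per segment the tachogram is cubic-resampled at 4 Hz and an FFT
periodogram integrated over the low-frequency (0.04–0.15 Hz) and
high-frequency (0.15–0.4 Hz) bands; LF/HF = LF power / HF power, averaged
over segments. The classical sympathovagal-balance index.

**IBS** (information-based similarity) — each segment is coarse-grained at
scale *s* (non-overlapping block means, n′ = ⌊n/s⌋), binarised into
increase(1)/decrease(0) symbols, and windowed into *m*-bit words. Adjacent
segments R₁, R₂ are compared by the rank order of their word frequencies:

  D(R₁, R₂) = Σᵢ |K₁(xᵢ) − K₂(xᵢ)| · w(xᵢ) / L,
  w(xᵢ) ∝ −p₁(xᵢ) log p₁(xᵢ) − p₂(xᵢ) log p₂(xᵢ),

with L the joint vocabulary size, Kⱼ the word's frequency rank in segment j
and the Shannon-term weights normalised to sum to 1. D ∈ [0, (L−1)/L];
identical fluctuation patterns give D = 0. The **IBS index** is the mean of
D over all adjacent pairs in 24 h.

**fApEn_IBS** — the sequence u(1..N) of adjacent-pair distances is itself a
time series; its fuzzy approximate entropy

  fApEn(M, r, N) = Φᴹ(r) − Φᴹ⁺¹(r)

(baseline-removed M-dimensional embedding, Chebyshev distances, Gaussian
membership exp(−(d/r)²), r = 0.25 × SD by default) measures how *complex*
the day-long similarity profile is. Defaults m = 2, s = 2, M = 2, r = 0.25.

CHF records score lower on all three indices. Screening uses a 1-D Fisher
discriminant per index (in-sample, CHF positive) and stratified 5-fold
cross-validated KNN (k = 5), random-forest and polynomial-SVM classifiers on
the feature triple, reporting confusion counts, accuracy/sensitivity/
specificity, and ROC/AUC, plus an accuracy sweep over m ∈ 2..6, s ∈ 1..7.

A synthetic-data module generates labelled 24-h cohorts (LF/HF tones at
0.1/0.3 Hz, white jitter, optional periodic fluctuation-pattern repetition)
so the entire chain is testable without downloads.

## Worked example

```sh
hrvibs run --synth-cohort 6,6 --duration 7200 --seed 42 --output-dir demo
head -5 demo/indices.csv
```

```
record_id,group,lf_hf,ibs,fapen_ibs
normal-000,normal,2.48918091,0.2848459127,1.742620076
normal-001,normal,2.531719636,0.3071177259,1.653075804
normal-002,normal,2.32954144,0.2658138385,1.75304788
normal-003,normal,2.238570661,0.2494439932,1.622573619
```

Each row is one record's feature triple: normal-like records sit near
LF/HF ≈ 2.3–2.5 (sympathetic-dominant balance), IBS ≈ 0.25–0.31 (adjacent
minutes have dissimilar fluctuation patterns) and fApEn_IBS ≈ 1.6–1.75
(a complex similarity profile). `demo/report.json` holds the screening
summary; for this cohort the fApEn_IBS group contrast is
mean ± SD = 1.658 ± 0.090 (normal) vs 1.338 ± 0.102 (CHF-like), Welch
t = 5.77, p = 1.9e-4, and every screen (Fisher per index, 5-fold RF on the
triple) classifies the two arms with 100 % accuracy and AUC 1.0 — the
synthetic arms are well separated by construction.

The same pipeline runs on real data: point `hrvibs indices --input-dir DIR`
at a directory of one-interval-per-line `.rr`/`.txt` files (seconds or
milliseconds, auto-detected), or build `RRSeries` objects from WFDB
annotations with `hrvibs.read_wfdb_intervals`.

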