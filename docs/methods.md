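# Methods

`emgonset` detects the onset of muscle activity in single-channel surface
EMG and benchmarks six detector families against signals with known onsets.
This note records the models, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Signals and preprocessing

A recording is a sampled amplitude series with a rate `fs` (the benchmark
convention is 2048 Hz)
and, for synthetic or annotated data, a gold onset time. Before any
detector runs, recordings pass a 4th-order Butterworth band-pass
(10–1000 Hz, upper edge capped at 0.49·fs for scaled rates) applied
forward–backward as second-order sections, so it is zero-lag. Zero-lag
filtering preserves event timing but smears energy symmetrically: detectors
may legitimately cross threshold a few milliseconds *before* an abrupt
onset. Edge handling is even-reflection padding; because a zero-phase
filter also leaves a boundary transient of roughly one cutoff period, the
envelope detector ignores threshold crossings inside that guard interval
(configurable, default `1/cutoff_hz` seconds).

All sample indices are 0-based and onset time is `index / fs`.

## Detector families

**Linear envelope.** Optional Teager–Kaiser preconditioning
(`psi[n] = x[n]^2 − x[n−1]x[n+1]`, endpoints replicated), full-wave
rectification, zero-lag 2nd-order Butterworth low-pass at a cutoff from
{2–20 Hz by 2, 25–50 Hz by 5}, threshold = mean + k·SD of the first 0.5 s
of the envelope with k ∈ {1, 2, 3, 15}, onset at the first strict
exceedance. TKEO runs before rectification because its output can be
negative on noise. If the baseline SD is zero the threshold degenerates to
the baseline mean, so an all-zero signal never detects.

**Sample entropy.** SampEn(m=2) in 32 ms windows stepped by 4 ms;
`−ln(A/B)` with Chebyshev distance, tolerance `r`, self-matches excluded,
both template sets over the same `n−m` starting points; `A=0` or `B=0`
yields an "undefined" sentinel and the window is skipped. Onset is the
first window of a run of 3 consecutive windows whose SampEn exceeds 0.6.
The tolerance is `r = 0.35 ×` the whole-recording SD. Scaling `r` to the
whole recording (burst included) is what makes the statistic an onset
detector at all: relative to a tolerance much larger than the baseline
noise, quiescent windows are highly regular (SampEn ≈ 0) while active EMG
stays far above the 0.6 threshold. The conventional r = 0.2 of a local SD
is scale-free and sits at SampEn ≈ 2.2 for *any* Gaussian window, which
would fire on the first baseline window; 0.35 was fixed from the
statistic's measured quiet/active separation at the benchmark's
signal-to-noise range before the evaluation suite was assembled, and the
3-window persistence rule suppresses isolated baseline excursions.

**AMOC likelihood tests.** At most one change in a Gaussian series, split
τ maximizing 2·ΔlogL for a change in the mean (pooled variance), the
variance (common estimated mean), or both; a change is declared when the
maximum exceeds an information-criterion penalty. The default penalty is
MBIC-style `(p+2)·log n` with `p` the number of changing parameters,
the conventional default for likelihood-based single-change tests;
a plain BIC `p·log n` is selectable but under it a null series of n=200
exceeds the penalty about half the time, which contradicts the method's
intent. Splits whose variance-model segment variance is exactly zero are
excluded (unbounded likelihood); a zero mean-model residual counts as a
perfect fit. Note the variance statistic's common mean is *estimated*: in
very short series a large-variance segment drags the mean and blurs the
boundary by a sample or two.

**Change-point models (CPM).** A standardized two-sample statistic
compared at every admissible split (startup guard 20 samples on either
side), maximized, and tested against a calibrated threshold; the reported
onset is always the earliest maximizing split, not the detection time.
Statistics: Student-t (mean), Bartlett (variance, with its small-sample
correction), Gaussian GLR (mean+variance), exponential GLR with and
without a Bartlett-type finite-sample divisor `1 + (1/k + 1/l − 1/t)/6`
(the exponential models require positive data and raise on raw EMG,
directing the caller to rectify), Mann–Whitney, Mood, and Cramér–von Mises
standardized by their exact null mean/SD, and two-sample
Kolmogorov–Smirnov scaled by `sqrt(kl/t)` (batch only). The all-splits
Cramér–von Mises scan runs in O(t log t) via Fenwick-tree prefix-count
moments; KS is O(t²).

*Batch mode* compares the maximum against the Monte-Carlo (1−α) null
quantile at the series length (2000 i.i.d. Gaussian replicates —
exponential for the exponential models — cached in-process; rank statistics
are distribution-free, parametric thresholds adopt the Gaussian reference
just as the original framework's tables do).

*Sequential mode* processes observations in order and signals when the
running maximum crosses a threshold curve h_t calibrated so the in-control
false-alarm hazard is ≈ 1/ARL₀ per observation. Curves are calibrated by
the conditional-quantile method (6000 in-control streams, alarmed streams
removed at each step, running-median smoothing) at ARL₀ ∈
{74, 150, 370, 1000, 3000} and extended to 5000 and 50,000 — the
benchmark's operating point — by a per-t linear fit in ln ARL₀, a
first-order growth law for maxima of standardized statistics. A coarse
table (t ≤ 1024, thresholds flat beyond; 4-decimal precision) ships with
the package and is interpolated log-linearly in ARL₀ and linearly in t;
`scripts/build_calibration.py` regenerates it. Extrapolated thresholds are
approximate — the realized ARL₀ at 50,000 may be off by tens of percent —
which shifts sequential detectors' conservatism slightly but is immaterial
for ranking detector families. Thresholds are monotone in ARL₀ by
construction.

**Bayesian product-partition change points.** The series is partitioned
into contiguous blocks with independent Gaussian means; priors on the
change probability p and the signal-to-noise ratio w = σ²/(σ²+σ₀²) are
uniform on [0, p₀] and [0, w₀], with w₀ = 0.2 throughout (the customary
value) and p₀ on the grid {0, 0.1, …, 1}. The Gibbs sampler resamples the
change indicator at every position against the exact conditional odds — a
ratio of incomplete-Beta integrals in p times a ratio of marginal-likelihood
integrals in w. Both are evaluated exactly: the p-ratio via regularized
incomplete beta functions (precomputed per change count), the w-integral
reduced by `u = Bw/(W+Bw)` to a regularized incomplete beta computed in
log space by a Lentz continued fraction inside the numba kernel. Block
sums update in O(1) per position through a boundary linked list; defaults
are 500 retained sweeps after 50 burn-in. The posterior change probability
at a position is the fraction of retained sweeps carrying a change there;
the posterior mean averages block sample means. Onset is the earliest
position at or above the chosen posterior threshold (strictly above when
the threshold is zero, so an empty posterior never detects).

At p₀ = 0 the conditional odds vanish linearly (leading order
`p₀·k/(k+1)` for k change points), so the limiting Gibbs dynamics keep
exactly those changes whose likelihood support is overwhelming, and a kept
change migrates only while moves improve the marginal likelihood by more
than the vanishing penalty, then pins. The implementation evaluates the
leading-order odds scaled by a fixed regularizer (10⁻¹²) that is
statistically inert: detection rates and error distributions are unchanged
across 10⁻¹⁰–10⁻¹⁴ (tested), so it represents the limit, not an eleventh
grid value. Design history, for the record: the raw leading coefficient
`k/(k+1)` used directly as odds floods pure noise with changes, and the
exact limiting posterior conditioned on a single change is too flat
(within ~2 nats across an onset neighborhood) to exceed useful thresholds;
the frozen-dynamics limit is the reading consistent with p₀ = 0 being the
conservative single-onset end of the grid *and* with onset thresholds of
60–95% remaining usable there.

## Synthetic EMG

Quiescent baseline is zero-mean Gaussian white noise (a modeling
assumption — real electrode baselines are band-limited and occasionally
artifact-laden; nothing here models artifacts). Active EMG is Gaussian
noise shaped to 20–450 Hz by default (scaled proportionally at reduced
rates). Two constructions:

* **Spliced:** 0.5 s of baseline concatenated with 1 s of active signal —
  3072 samples at 2048 Hz with an abrupt objective onset at exactly 0.5 s,
  reproducing the benchmark bookkeeping. `extract_simulated_from_recording`
  builds the same trial from a longer annotated recording, taking the
  active block 0.5 s after the annotated onset.
* **Experimental-like:** baseline throughout, plus an active component
  whose envelope rises linearly (optionally logistically) over a ramp
  (default 100 ms) to a plateau; the gold onset is the ramp start, where
  the activity amplitude is still zero, so every detector carries a small
  positive lag by construction.

SNR is an amplitude ratio — max |x| over the trial divided by the RMS of
the first 500 ms — shared between the generator and the evaluation
statistic. The plateau SD needed for a requested SNR comes from the
expected peak factor of a band-limited Gaussian process,
`sqrt(2 ln m) + γ/sqrt(2 ln m)` with `m = 2·bandwidth·duration`
independent extremes, net of the baseline variance underneath the burst.
Requested SNRs below the bare-noise peak factor (~3.5) are not realizable
by construction. Everything is reproducible from (spec, seed) via spawned
`SeedSequence` streams.

## Evaluation pipeline

The grid replicates the benchmark's 605 configurations: 64 envelope + 64
TKEO + 1 SampEn (129 standard) and 6 AMOC + 16 sequential CPM + 14 batch
CPM + 440 Bayesian (11 p₀ × 20 thresholds × raw/rectified) statistical
entries. Bayesian entries sharing (p₀, rectification) reuse one sampler
run per trial. Detector errors are captured per (trial, configuration) as
non-detections with a note; a journal file makes sweeps resumable.

Per configuration: RMSE against gold onsets over detected trials
(undetected trials are excluded pairwise; zero detections give an infinite
sentinel), a no-onset rate, a first-index rate (onset at sample 0), and
the mean difference from gold with a parametric t-based 95% CI.
Down-selection: (1) keep configurations with RMSE at or below the 10%
linear-interpolation quantile, ties kept; (2) drop those missing or firing
at the first index on strictly more than 25% of trials; (3) regress gold
onset on (algorithm onset, trial SNR) by OLS and drop configurations with
a two-sided SNR coefficient p < 0.05 — applied only when the gold onset
varies (for fixed-onset spliced sets the regression is degenerate, so the
phase is skipped, mirroring the protocol for fixed-onset sets).
Configurations with fewer
than 10 detections or a rank-deficient design are retained untested.
Survivors are ranked by CI width (reliability); accuracy is the mean
difference's proximity to zero.

`headline_benchmark` runs the full grid on 100 experimental-like trials
with gold onsets uniform on 0.5–0.75 s within 1.75 s trials and SNRs
uniform on 2–78 (the benchmark's observed range; only the range is known,
so a uniform span is used). It is scaled to 512 Hz so the sweep fits in a
few minutes on one CPU; sweep counts are the 500/50 defaults. On this
benchmark the narrowest-CI survivors are Bayesian (p₀ = 0, rectified)
configurations across the full threshold grid — the package-level analog
of the finding that conservative Bayesian change-point analysis on
rectified EMG is the most reliable single-onset detector.

## What the synthetic benchmark shows — and does not

Passing tests establish that each detector implements its definition
(verified against brute-force oracles), that calibrated error rates hold
under the stated nulls, and that the evaluation pipeline ranks detector
families on Gaussian-burst surrogates the way the underlying study ranked
them on human recordings. The surrogates contain no motor-unit structure,
no movement artifacts, no baseline drift, and no rater disagreement about
the gold standard, so absolute error magnitudes here (milliseconds at high
SNR) underestimate what heterogeneous laboratory data produce, and results
at SNR below ~4 are dominated by the detectability floor of every family.

## Numerical and convention notes

* Strict (">") threshold exceedance everywhere; all-zero inputs never
  detect.
* Earliest-split tie-breaking for every argmax over change points.
* Sequential onsets satisfy `startup ≤ τ ≤ t − startup`; batch likewise
  within the full series.
* Batch/sequential calibration uses a fixed internal seed: thresholds are
  part of the method, not of an analysis, so analysis seeds do not move
  them.
* The text signal format stores `%.17g` amplitudes — exact double-precision
  round-trip — with `# key=value` headers for fs, labels, and gold onset.
* Known limitations: single onset per trial (no burst segmentation);
  univariate mean-change Bayesian model only; sequential thresholds at
  ARL₀ = 50,000 are extrapolated, not directly calibrated.
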