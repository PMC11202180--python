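# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mtrrp`, in the order the analysis runs.

## Signal simulation

**Fractional Brownian motion.** fGn (the stationary increment process of
fBm with Hurst exponent H) is sampled exactly by circulant embedding of
its covariance γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})
(Davies–Harte); the fBm path is the cumulative sum. The embedding is
nonnegative definite for all H ∈ (0, 1) at the sizes used here; a
Cholesky factorization of the exact covariance is kept as a fallback for
pathological cases. Because the construction is exact, the k-step
increment variance scales as k^{2H} and a log–log regression over
k ∈ {1…64} recovers H within ±0.1 at n = 8192 (test-verified). Any exact
method would do: downstream analyses depend only on the Hurst property,
not on the synthesis algorithm.

**Reference signals.** White noise (i.i.d. standard Gaussian), random
walk (its cumulative sum; the canonical memoryless H = 0.5 process),
harmonic oscillation (the phase is computed modulo the integer period, so
periodicity is bit-exact), and the logistic map at r = 4 after a fixed
1000-step burn-in (chaotic, values in [0, 1]).

**Synthetic EEG cohort.** Each of the 19 channels (10–20 montage) is a
sum of five band-limited oscillations — Gaussian noise band-passed into
the conventional Delta/Theta/Alpha/Beta/Gamma bands — plus a stationary
fGn background. Defaults emulate resting EEG as a 1/f-dominated broadband
process with an alpha peak: oscillation amplitudes
(0.5, 0.4, 1.0, 0.3, 0.2) against a noise amplitude of 4, so the fractal
background dominates the power inside every analysis band while the
alpha bump remains visible against it. That dominance is what makes the
injected group effect detectable: the
occipital channels (O1, O2) draw their background from a group-specific
Hurst exponent (defaults 0.7 for HC, 0.3 for the AD-like group), and
because fGn's spectral density varies with H, the in-band
noise-to-oscillation ratio — and through it every MTRRP metric — differs
between groups, most strongly in the Delta and Beta bands. If the
oscillations dominated instead, band-passing would wash the effect out
(the MTRRP metrics are deliberately scale-free, so overall amplitude
carries no information).

What the generator does **not** emulate: volume conduction and
inter-channel correlation, nonstationarity, eye/jaw artifacts, line
noise, or any physiological forward model. Passing tests therefore show
that the pipeline detects a band-limited fractal group difference at
realistic SNR — not that it would detect dementia in clinical
recordings.

Determinism: every generator is a pure function of (spec, seed);
per-subject and per-channel streams are spawned from the root seed with
`numpy.random.SeedSequence`, so results are independent of generation
order.

## Recurrence analysis

Delay embedding uses vectors X_i = (x_i, x_{i+τ}, …, x_{i+(M−1)τ}).
τ defaults to the first lag where the (biased, FFT-computed)
autocorrelation drops below 1/e, searched up to lag n/4, with the first
local minimum of the lagged mutual information (16-bin histogram) as an
alternative; M comes from the Kennel false-nearest-neighbour criterion
(ratio threshold 15, capped at dimension 10). Zero-distance neighbours
(exact repeats, common in synthetic periodic signals) count as true
neighbours only when the next coordinate also agrees.

The recurrence comparison is inclusive (distance ≤ ε), the matrix is
symmetric, and the Theiler window defaults to 0 — the diagonal is counted,
matching a recurrence rate that saturates at exactly 1. Distances are
Euclidean by default (Chebyshev by flag; identical for M = 1). The dense
matrix is materialized only up to 5000 vectors; recurrence *rates* are
accumulated blockwise (2048-point tiles of the upper triangle) at any
length, bit-identically to the dense path (test-verified).

## MTRRP and its metrics

The series is min–max normalized (Eq. above; constant series are
rejected), and thresholds follow ε_k = ε_min + k·Q·σ with ε_min = 0.1,
Q = 0.3, truncated at 1.0, requiring at least 3 rungs. M = 2 by default
(2–3 recommended; higher dimensions thin the phase space without changing
the ordering of the metrics).

**Counting conventions.** `counting="matrix"` (default) divides the number
of marked cells of the full symmetric matrix, diagonal included, by n² —
RR rises to 1. `counting="pairs"` counts each off-diagonal recurrent pair
once among all n² cells, so RR saturates near ½. The conventions differ
only by an affine map and leave RRG/RH orderings intact; the pairs
convention is the one under which the fitted model constant α of
classical Brownian motion comes out at its conventional value 0.5 (see
below).

**Epoching.** Long series are split into non-overlapping 2000-sample
epochs and per-epoch recurrence rates are averaged per threshold
(automatic above 5000 samples, configurable). This keeps the O(n²)
distance computation tractable and, for EEG, averages over slow
nonstationarity. Normalization and threshold construction use the whole
series, so epochs share a common scale.

**Recurrence Rate Gradient.** OLS slope of RR against ε over the initial
segment, cut off either at a uniform user threshold or per series at the
stabilization point — the smallest ε where RR reaches 95% of the final
recurrence rate (fraction configurable). At least 3 points must fall in
the fit region; a curve that saturates at the first rung is reported as a
fit error rather than a gradient.

**Recurrence Hurst.** The model RR(ε) = α(1 − RH·ln ε) (natural log;
α a user-chosen constant, default 0.5) is the unique reading of the
defining relations under which the forward model and the pointwise
inverse h = (1 − RR/α)/ln ε are mutually consistent. Estimation choices,
in decreasing faithfulness to the fBm ordering they must reproduce:

* `slope` (default): RH = −(slope of RR vs ln ε over the usable
  pre-plateau points)/α. Across fBm sweeps H = 0.1…0.9 the per-H mean
  (20 seeds each, n = 2048) tracks the generator H with
  |Spearman ρ| ≥ 0.8 (test-verified).
* `median` / `mean`: aggregate the pointwise h_k. These are retained for
  completeness but are dominated by the blow-up of h_k as ε → 1
  (ln ε → 0), which flattens the dependence on H; they should only be
  used on curves far from saturation.

Points with ε = 1 (log divisor 0) or RR = 1 are skipped. The pre-plateau
cutoff is the RRG stabilization point; when that would leave fewer than
3 usable points (as on exactly synthesized model curves, which *decrease*
in ε for RH > 0) all valid points are used instead — this keeps the exact
algebraic round-trip (synthesize from the model, recover RH to 1e−9)
intact for every estimator. Sign convention: ln ε < 0 below ε = 1, so RH
is negative for rising curves; values are reported as computed with no
sign flip, and only comparisons between signals carry meaning.

**Model constant α.** `fit_rr_model` fits (α, RH) jointly; the model is
linear in (α, −α·RH), so the least-squares solution is the regression of
RR on ln ε and α is the fitted value at ε = 1 — i.e. the saturation level
the pre-plateau trend extrapolates to. Under matrix counting that is ≈ 1
by construction for any signal; under pair counting it is ≈ ½, and for
classical Brownian motion (H = 0.5, M = 2, τ from autocorrelation) the
fitted mean over 20 seeds comes out at ≈ 0.51 (recomputed from scratch
by `scripts/acceptance.py`) — which is why the package reads
the conventional "α = 0.5 for classical Brownian motion" as identifying
the pair-counting convention, and why the calibration study uses it.

**Recurrence Complexity** is the exact product RRG × RH (asserted
bit-for-bit wherever the two are produced together).

## Adaptive fractal analysis

The profile u (input series, or its cumulative sum when
`input_is_increments=True` — the integrated-vs-increment choice is the
classic off-by-one-in-H trap and is always the caller's explicit
decision) is covered by local polynomial fits (order 1 by default) on
windows of odd length W = 2h+1 stepping by h, with a final segment
anchored at the series end. Consecutive fits are blended over their
overlap with linearly decaying, center-peaked weights; shared junction
samples receive identical values from both fits, so the stitched trend
has no jumps at segment boundaries. F(W) is the RMS of u − v, and H is
the OLS slope of log₂F on log₂W over a dyadic ladder of odd windows from
5 to n/8 (the largest window may never exceed n/4). Residuals below
1e−10 of the profile's scale are treated as exactly polynomial input and
rejected rather than fitted. F scales linearly with the signal, so H is
scale-invariant.

Calibration (test-verified, n = 8192, 20 seeds per condition): random
walks give mean Ĥ = 0.50 ± 0.1, and mean |Ĥ − H| ≤ 0.15 across
H ∈ {0.2, 0.35, 0.5, 0.65, 0.8}.

## EEG feature extraction

Channels are filtered with a 4th-order zero-phase (forward–backward)
Butterworth band-pass per band — zero-phase so that band-dependent group
delays cannot shift epochs between bands. Band edges are the conventional
Delta 0.5–4, Theta 4–8, Alpha 8–13, Beta 13–30, Gamma 30–45 Hz, inside
the usual 0.5–45 Hz analysis envelope, which is also exposed as an
optional `FullBand` (off by default, keeping the canonical 285-column
table). Per subject × channel × band the MTRRP metric triple is computed
on the filtered signal (epoched as above) and stored as
`channel.band.metric` columns; the table is invariant to channel ordering
and, because of the min–max normalization, to any per-recording gain
(test: a ×3 gain changes no feature by more than 1e−9).

Inputs are expected to be cleaned EEG; re-referencing and artifact
removal (ASR, ICA/ICLabel) are upstream preprocessing, out of scope here.
When loading real recordings the first 300 s are used (configurable), via
the `mne` EDF reader.

## Statistics and classification

One-way ANOVA per feature (scipy), with partial
η² = F·df₁/(F·df₁ + df₂) and Bonferroni correction across the family of
tests actually run; pairwise post-hoc t-tests are Bonferroni-adjusted
within the set of group pairs. Feature ranking is |Pearson r| against 0/1
labels, ties broken toward the earlier column, zero-variance features
scored 0 with a warning.

The classifier is a linear SVM with C = 1 (a conventional choice in the
small-n/large-p regime; kernel and C configurable) under leave-one-out
cross-validation. Feature ranking and standardization are recomputed
inside every fold on the training rows only; a `global` selection mode
exists to reproduce the optimistic variant but is off by default. The
permutation test shuffles labels and reruns the complete protocol —
including in-fold re-selection — per shuffle, with
p = (1 + #{null ≥ observed})/(1 + n_perm); p can never be smaller than
1/(n_perm + 1).

## Problem sizes of the validation studies

The simulation studies fix their own desk-scale conditions: fBm length
8192 for AFA calibration and 4096 for the model-constant study (20 seeds
each); 2048 for the Recurrence-Hurst sweep (20 seeds per H); and a
synthetic cohort of 15 + 15 subjects, 19 channels, 60 s at 128 Hz
(Nyquist comfortably above the Gamma band), analysed in 1000-sample
epochs, with 99 permutations for the null. The end-to-end study asserts: a 285-column table, a largest
occipital Recurrence-Complexity effect |d| > 0.8, LOOCV accuracy above
80% with permutation p ≤ 0.01, and a permutation null centred in the
chance band.

## Known limitations

* The MTRRP metrics are relative quantities; absolute values depend on
  the threshold ladder, embedding and counting convention, so only
  within-study comparisons are meaningful.
* The pointwise RH aggregators are unreliable near curve saturation (see
  above).
* The Recurrence-Hurst/H relationship is monotone but compressed; RH is
  a ranking statistic, not an unbiased estimator of H (AFA is the
  estimator).
* No multiclass classification: multi-group tasks are handled as binary
  contrasts (e.g. controls vs pooled patients).
* Epoch averaging assumes approximate stationarity within 2000-sample
  epochs; strongly nonstationary segments should be cleaned or excluded
  upstream.
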