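# mtrrp — multi-threshold recurrence rate analysis of time series and EEG

`mtrrp` quantifies the structural complexity of a time series by asking a
simple question at many scales: *how often does the system revisit a
previous state, and how quickly does that recurrence probability grow as
the notion of "revisit" is relaxed?* It is aimed at researchers analysing
nonlinear dynamics in physiological recordings — resting-state EEG in
particular — who want compact, scale-free complexity features for group
statistics and classification.

## The method

For a series *x(1)…x(n)*, min–max normalized to [0, 1] and delay-embedded
as *X_i = (x_i, x_{i+τ}, …, x_{i+(M−1)τ})*, the recurrence plot at
threshold ε marks the pairs

&nbsp;&nbsp;&nbsp;&nbsp;R_{ij}(ε) = 1 iff ‖X_i − X_j‖ ≤ ε,

and the recurrence rate RR(ε) is the fraction of marked cells. Evaluating
RR over an increasing ladder of thresholds

&nbsp;&nbsp;&nbsp;&nbsp;ε_k = ε_min + k·Q·σ  (ε_min = 0.1, Q = 0.3, σ = sd of the
normalized series, ε_k ≤ 1)

gives the **multi-threshold recurrence rate plot (MTRRP)**, a monotone
curve summarized by three metrics:

* **Recurrence Rate Gradient (RRG)** — the OLS slope of RR against ε over
  the initial, pre-plateau segment of the curve. Noise-like signals
  accumulate recurrences quickly (steep slope); strongly persistent
  signals recur early and flatten.
* **Recurrence Hurst (RH)** — a Hurst-like exponent from the model
  RR(ε) = α·(1 − RH·ln ε) with the model constant α (default 0.5); the
  default estimator reads RH off the fitted log-slope,
  RH = −(dRR/d ln ε)/α. For normalized data RH is negative on rising
  curves; its ordering tracks the Hurst exponent of the underlying
  process.
* **Recurrence Complexity (RC = RRG × RH)** — the product joining local
  randomness with long-range persistence.

The package also provides an independent Hurst estimator (adaptive
fractal analysis, AFA: RMS residuals of an adaptively stitched local-linear
trend across window sizes W, with F(W) ~ W^H), exact fractional-Brownian-
motion simulation (circulant embedding), a synthetic 19-channel EEG cohort
generator with a controllable occipital group effect, Butterworth band-pass
feature extraction into a subjects × (channel, band, metric) table
(19 × 5 × 3 = 285 columns), and the classification protocol: Pearson
top-*k* feature selection, linear SVM with leave-one-out cross-validation
(selection and standardization recomputed inside every fold), and a
label-shuffling permutation test.

## Worked example

```python
import numpy as np
import mtrrp as M

# a persistent fBm path and a white-noise series of equal length
fbm   = M.generate_fbm(M.FbmSpec(hurst=0.8, n=4096, seed=1))
noise = M.generate_reference("white_noise", 4096, seed=1)

for name, ts in [("fBm H=0.8", fbm), ("white noise", noise)]:
    curve = M.compute_mtrrp(ts.samples)
    t = M.metric_triple(curve)
    afa = M.afa_fit(ts.samples, input_is_increments=(name == "white noise"))
    print(f"{name:12s} RRG={t.rrg:6.3f}  RH={t.rh:6.3f}  RC={t.rc:6.3f}  "
          f"AFA H={afa.hurst:5.3f}")
```

prints

```
fBm H=0.8    RRG= 0.921  RH=-0.719  RC=-0.662  AFA H=0.740
white noise  RRG= 2.133  RH=-1.133  RC=-2.416  AFA H=0.482
```

The noise series has more than twice the recurrence-rate gradient of the
persistent fBm (local randomness), a more negative recurrence Hurst, and
hence a much more negative recurrence complexity; AFA independently
recovers H ≈ 0.74 for the fBm path and H ≈ 0.5 for the integrated noise
(a memoryless random walk). The same metrics, computed per channel and
frequency band, are the features of the EEG pipeline:

```python
spec = M.SyntheticEEGSpec(n_per_group=15, sampling_rate=128.0,
                          duration=60.0, seed=11)
table = M.extract_features(M.generate_synthetic_eeg(spec),
                           epoch_length=1000, max_duration=None)
y = table.encoded_labels("AD")
report = M.svm_loocv(table.X, y, k=50, seed=7)
perm = M.permutation_test(table.X, y, n_perm=99, k=50, seed=7)
print(table.frame.shape, round(report.accuracy, 3), perm.p_value)
```

which prints `(30, 285) 0.833 0.01`: the 285-column feature table, 83%
leave-one-out accuracy on the injected occipital group effect, and the
smallest p-value attainable with 99 permutations.

A command-line interface mirrors these stages
(`mtrrp simulate-fbm | simulate-eeg | rp | mtrrp | afa | extract |
classify | anova`); see `mtrrp --help`.

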