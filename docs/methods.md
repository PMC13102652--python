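# Methods

## Decoding model

A trial is X ∈ ℝ^{C×T} (C channels, T samples at 250 Hz). The pipeline:

1. **Filter bank.** 8–32 Hz is partitioned into F = 6 contiguous 4-Hz
   bands. Each band is isolated with a 4th-order Butterworth band-pass
   applied forward–backward (`sosfiltfilt`, odd-reflection padding of
   three filter lengths), i.e. zero phase with effective order 8. The
   filter family/order are configurable; zero-phase filtering is the
   default because group delay would shift ERD/ERS latencies that the
   temporal convolutions later exploit.

2. **One-vs-rest CSP.** Per (class k, band f): Σ_k is the average of
   per-trial covariances over class-k training trials, Σ_rest the average
   over all other training trials (trial-weighted pooling). Per-trial
   covariance is XcXcᵀ/T after per-channel mean removal, plus a relative
   ridge 1e-8·(trace/C)·I so a degenerate channel cannot break positive
   definiteness. No per-trial trace normalization by default (the plain
   average estimator); `trace_normalize=True` enables the common
   power-equalizing variant, and `rest_pooling` switches Σ_rest between
   trial-weighted pooling (default) and the unweighted mean of the other
   class means (identical for balanced designs). The generalized
   eigenproblem Σ_k w = λ Σ_rest w is solved with `scipy.linalg.eigh`. Columns kept: m largest-λ
   (descending) then m smallest-λ (ascending); each column is scaled to
   unit norm (making filters invariant to a global rescaling of the data)
   and sign-fixed so its largest-magnitude coefficient is positive — a
   pure determinism convention. If Σ_k ≈ Σ_rest up to scale (all λ
   equal), the first 2m solver-order eigenvectors are returned with a
   warning rather than failing.

3. **Fusion.** All K·F projections are applied to every trial and the
   projected *time series* are stacked class-major, band, component:
   D = K·F·2m virtual channels (48 for K=4, F=6, m=1; 144 for m=3). Each
   virtual channel is tagged (class, band, component) so saliency can be
   aggregated later. 2m ≤ C is enforced — e.g. m = 12 on a 22-channel
   montage is rejected.

4. **Backbone.** Input [B, 1, D, T] → batch norm (one input map) →
   zero-pad time (32, 31) → Conv(1×64) to F1 = 16 maps → BN →
   grouped Conv(D×1), 16 groups, depth multiplier 2 → 32 maps → BN, ELU,
   AvgPool(1×4), dropout 0.5 → zero-pad (7, 8) → depthwise Conv(1×16) →
   pointwise Conv(1×1) to F2 = 32 → BN, ELU, AvgPool(1×8), dropout →
   channel attention → flatten (32·T//32) → dense 128 + BN + ReLU +
   dropout → dense K. Pooling floors (T → T//4 → T//32); convolutions
   before a batch norm carry no bias; no max-norm constraints. The
   attention gate concatenates global average and max pooling (64),
   passes a shared bottleneck 64→32→16→32 with ReLU/ReLU/sigmoid, and
   rescales the 32 maps multiplicatively; gates are strictly in (0, 1).

5. **Training.** Adam (β = 0.9/0.999, ε = 1e-8), lr 0.001, batch 32,
   cross-entropy; batches reshuffled per epoch from the run seed,
   drop-last disabled, no early stopping. Initialization is fan-in
   uniform, batch-norm scale 1 / shift 0, fully seeded. Default 300
   epochs; the cross-validated experiments in this repository use 100
   (training on the synthetic presets converges well before that, and the
   choice is recorded with each report).

## Numerical implementation of the network

No deep-learning framework is used: layers are NumPy with hand-written
backward passes, float32 throughout. Two exact execution paths exist for
the entry block (input BN → temporal conv → BN → depthwise):

* a *reference* path that materializes the [B, F1, D, T] tensor layer by
  layer, and
* a *fused* path exploiting that the F1 temporal kernels are shared
  across the D rows while the depthwise stage contracts D immediately:
  the D-contraction is applied first (one matmul), the temporal
  convolution then runs per map in the frequency domain, and both batch
  norms enter as per-map affine maps whose batch statistics — and all
  gradient contractions — are recovered from per-trial caches (64×64
  window Gram matrices, window sums, and trial rFFTs). Gradients are
  exact, including the batch-statistics terms of both batch norms.

The two paths share parameters and running statistics; the suite asserts
equality of outputs and of every parameter gradient, and the backward
pass is further validated against central finite differences. The fused
path is ~50× faster at D = 48 and is used for fitting and prediction;
the reference path backs the input-gradient (saliency) computation.

## Evaluation protocol

Stratified k-fold (default 5): within each class, trials are shuffled by
the fold seed and dealt round-robin, so per-class counts differ by ≤ 1
and every fold contains every class. A fresh estimator clone is fitted
per fold on training trials only — leakage control is structural, and the
report records the exact train indices per fold so it is auditable.
Per-subject aggregation concatenates fold predictions and sums confusion
matrices; accuracy mean ± SD is across folds. `grid_search_m` runs the CV
per m ∈ {1..5}, skips infeasible m (2m > C) with a warning, and breaks
ties toward the smallest m.

Statistics: paired t-test t = mean(d)/(sd(d)/√n) with sd using n−1,
two-sided p from t_{n−1}; Cohen's d uses the paired standardizer
mean(d)/sd(d) (identical vectors raise rather than returning 0). F1 is
computed per class with the zero-division→0 convention; micro-F1 equals
accuracy, which the suite asserts as an identity. Welch band power uses
1-s Hann segments with 50 % overlap, integrated with the trapezoid rule
over band-interior bins. Saliency is the absolute gradient of the
true-class logit w.r.t. the input, averaged over time then trials, and
aggregated by band and by (CSP class × band) via the virtual-channel
index map, normalized to percentages summing to 100 per subject.

## Synthetic ERD/ERS generator

Each trial is x(t) = Σⱼ pⱼ gⱼ(t) sⱼ(t) + noise: K = 4 unit-norm
orthogonal spatial patterns (QR of a seeded Gaussian matrix), one
band-limited source per class — white noise shaped in the frequency
domain by the 4th-order Butterworth magnitude response of its band.
Frequency-domain shaping (rather than time-domain filtering) makes the
sources exactly stationary over the window, which matters in mode B
below. Noise is a fixed random C×C mixture of white backgrounds
(spatially correlated, like real EEG), scaled per trial to the configured
signal-to-noise ratio.

* **Mode A** plants the classic spatial-variance (ERD/ERS) signature: on
  a class-k trial the class-k source has `erd_gain` (default 4) times the
  variance of the others. This is what CSP is built for; at high SNR the
  fitted top filter, mapped through the forward model A = Σw/(wᵀΣw),
  recovers the planted pattern with |cos| > 0.9.
* **Mode B** plants *timing only*: every source in the trial is gated by
  one common raised-cosine burst whose onset latency is class-specific,
  with mean-square amplitude exactly 1. Because all classes share the
  identical burst shape (equal duty cycle, amplitude and modulation
  sidebands) and the burst stays clear of the window edges, the expected
  variance of every source in every band is class-invariant — simpler
  envelope designs (e.g. an onset ramp sustained to the trial end, or a
  circularly wrapped burst) leak class information into band-wise
  variances through duty-cycle-dependent sidebands or edge losses of the
  analysis filters, and were rejected after measuring exactly that.
  Log-variance pipelines are blind by construction (verified by ANOVA on
  the planted components and by FBCSP scoring at chance); classifiers
  that see the time course are not. This is the package's testable form
  of the claim that discarding temporal dynamics discards class
  information.

Recorded presets (stable seeds, 8 channels, 40 trials/class, 250 Hz):
`easy-A` (2-s trials, 12 dB SNR), `hard-A` (0 dB), `temporal-B` (3-s
trials, onsets 0.5/0.8/1.1/1.4 s, 1-s burst, 0.25-s ramp, 12 dB). The
2–3 s windows are standard MI analysis windows and keep full
cross-validated runs desk-scale; `SynthConfig` defaults describe a 4-s
window matching common cue-aligned epoching.

What the generator does *not* emulate: volume-conduction forward models,
non-orthogonal/overlapping source patterns, artifacts (EOG/EMG),
non-stationarity across trials or sessions, and inter-subject
variability. Passing tests on these presets therefore demonstrate
correctness of the machinery and the spatial/temporal dissociation logic,
not expected accuracy on real EEG.

## Known limitations

* D grows as K·F·2m; the backbone's cost is linear in D·T and the fused
  path assumes the architecture's specific entry-block structure.
* The single-filter-set ablation (FBEEGNet) needs a choice of which
  one-vs-rest problem supplies the filters; `reference_class` (default 0)
  makes that choice explicit and configurable, as the original choice is
  not recoverable.
* The FBCSP baseline uses a shrinkage LDA (lsqr, Ledoit–Wolf auto
  shrinkage) rather than the historical mutual-information feature
  selection + Bayesian classifier.
* Batch-norm statistics in eval mode come from running averages with
  momentum 0.1; very short training runs can leave them close to their
  initialization.
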