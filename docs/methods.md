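# Methods

This note records the models, numerical choices and limitations behind the
package, in the order the pipeline runs.

## Synthetic data model

The generator emulates a 4-channel affective recording session at 200 Hz.
Each emotion class is an `EmotionRegime` — a small set of autonomic
parameters:

| emotion  | HR (bpm) | HR sd | SCR/min | tonic GSR | EMG bursts/min | EMG gain |
|----------|---------|-------|---------|-----------|----------------|----------|
| pleasure | 70      | 4     | 4       | 8         | 4              | 1.5      |
| fear     | 95      | 8     | 10      | 12        | 10             | 3.0      |
| sadness  | 60      | 2     | 2       | 6         | 2              | 1.0      |
| anger    | 85      | 6     | 7       | 10        | 8              | 2.5      |

These defaults place the classes in the physiologically plausible ordering
(fear/anger high-arousal, sadness lowest) and make them separable mainly
through heart rate/HRV, SCR rate and EMG activity — the premise that ANS
features discriminate emotion. Per-participant jitter (HR ±2 bpm, rates
±15%) creates between-subject variation.

Waveform models: ECG beats are five Gaussian bumps (P, Q, R, S, T) at fixed
offsets (−0.2, −0.04, 0, 0.04, 0.25 s) and amplitudes (0.15, −0.1, 1.0,
−0.2, 0.3), placed at RR intervals max(0.3 s, N(60/HR, sd)); PPG pulses are
two-sided Gaussians (30 ms systolic rise, 100 ms diastolic decay) delayed
250 ms from each R; GSR is a tonic level plus Poisson SCR events with ~1 s
rise and ~4 s decay; EMG is white noise amplitude-modulated by Poisson
burst envelopes. Baseline wander is a sinusoid (default 0.1 units at
0.15 Hz) and a scaled EMG copy (gain 0.05) leaks into ECG as cross-channel
interference for the LMS canceller to remove. One root seed spawns
per-channel substreams, so records are bit-identical given (config, seed).

What the generator does **not** emulate: real PQRST morphology and its
beat-to-beat variation, respiratory sinus arrhythmia, electrode motion
artifacts, nonstationary drift, or correlated inter-channel physiology
beyond the shared beat times. Passing tests therefore demonstrate the
pipeline's correctness and discriminative machinery under controlled
conditions, not clinical-grade performance on recorded humans.

## Preprocessing

* **LMS canceller** — 5-tap FIR, per-sample update w ← w + μ e x with
  μ = 1e-6; EMG is the reference channel for ECG (the wiring is
  configurable; the pairing is a choice, since any channel pair may
  interfere in principle).
* **Segmentation** — exactly 20.0 s non-overlapping windows fully inside
  one label interval; partial trailing windows are discarded and logged.
* **Butterworth low-pass** — order 4 (steep roll-off without ringing),
  zero-phase via forward–backward filtering; 0.4 Hz for EMG, 0.3 Hz for
  GSR. The EMG channel is rectified before filtering: a 0.4 Hz low-pass on
  a raw zero-mean EMG would null the channel, so the filter is read as
  acting on the activity envelope.
* **Moving average** — centred, reflected edges, default 5 samples (25 ms)
  for ECG. PPG instead gets a 15 Hz zero-phase low-pass: the pulse band
  ends well below 15 Hz, and removing broadband noise there is what keeps
  the scale-4 detail (a 25–50 Hz band at 200 Hz) dominated by the systolic
  apex rather than by noise.

## Wavelet detection

The undecimated (à-trous) transform is computed through explicitly composed
equivalent filters: the level-j detail kernel is
lo₁ ∗ … ∗ lo_{j−1} ∗ hi_j with each stage upsampled by zero insertion, and
the level-n approximation kernel is the product of low-passes (normalised
to unit sum, so the baseline estimate has DC gain 1). Two numerical choices
matter:

* **Centroid alignment.** db/sym analysis filters are asymmetric; through a
  7-level cascade their group delay reaches hundreds of samples. Each
  composed kernel is applied anchored at its (energy) centroid so details
  and the baseline estimate stay time-aligned with the input — the
  zero-phase property the detector's zero-crossing rule needs.
* **Odd reflection padding.** Boundaries are extended anti-symmetrically
  (continuous value *and* slope). Plain even reflection leaves a
  derivative kink that the band-pass kernels register as a large spurious
  extremum at segment edges, which inflates the detail RMS and starves the
  relative threshold.

Detection: local extrema of the detail exceeding 2.0 × RMS(detail) are
paired (opposite signs within 0.12 s for ECG / 0.25 s for PPG); the peak
candidate is the zero crossing between the pair, refined to the local
signal maximum within ±50 ms (ECG) / ±80 ms (PPG) — this absorbs the
residual phase of the asymmetric wavelets; polarity is configurable for
negative-going waves. A refractory period (0.2 s ECG, 0.3 s PPG) suppresses
duplicates. Thresholding relative to the detail RMS makes detection
invariant to amplitude scaling. P/Q/S/T are then located as signal extrema
in fixed per-beat windows (P: max in [R−200, R−60] ms, Q: min in [R−60, R),
S: min in (R, R+60], T: max in (R+80, R+350] ms); beats whose windows leave
the segment are dropped whole, keeping the five index arrays beat-aligned.

"Scale 8" and "scale 4" are read as dyadic scales 2³ and 2² of the
undecimated transform — the classic modulus-maxima QRS scheme, where an
opposite-sign extremum pair with a zero crossing at the peak is the
signature — and the 7-/5-level decompositions as the separate
baseline-removal depth.

## Feature catalog (136 columns)

ECG (81): eight interval series (RR, PP, QQ, SS, TT within-wave; PQ, QS, ST
within-beat; all ms) × {mean, median, sample std, min, max, range}; three
amplitude series (P, R, S) × the same six; HRV = stats6(RR) + pNN50
(strict > 50 ms) + spectral mean; HRV distribution = stats6 over the
nonzero histogram bin counts (7.8125 ms bins anchored at 0) + triangular
index N/max(bin count). GSR and EMG (21 each): raw, first and second
difference × {mean, median, std, min, max, minRatio, maxRatio}. PPG (13):
pulse-amplitude stats6, pulse-interval stats6, interval spectral mean.

Choices where the catalog's source semantics are underdocumented:

* **minRatio/maxRatio** — fraction of samples within 10% of the range of
  the min/max (closed bands; both 1 for a constant series). The band width
  is configurable.
* **Spectral mean** — mean magnitude of the DFT of the mean-removed
  tachogram after linear-interpolation resampling at 4 Hz (standard HRV
  practice; a constant tachogram gives exactly 0).
* **HRV distribution stats** — computed over the nonzero histogram counts;
  which quantity the six stats summarise is otherwise ambiguous.
* Sample (n−1) standard deviation throughout; intervals in ms, amplitudes
  in signal units, ratios dimensionless.

The variance filter drops columns with population variance below
0.8×(1−0.8) = 0.16 and returns the boolean mask; in strict CV the filter is
re-fitted per training fold and the mask applied to the held-out rows.

## Kernel PCA

Features are standardised (training mean/std) before the kernel — kernel
-space centering alone does not equalise feature scales, and the catalog
mixes ms, conductance units and dimensionless ratios. The bandwidth
defaults to γ = 1/(2σ²) = 1/(d·var(X)) on the standardised training matrix
(≈ 1/d after standardisation); a median-pairwise-distance heuristic is
available. Eigenvectors with λ ≤ 1e-10·λ_max are discarded; the sign of
each α is fixed by making its first non-negligible entry positive, so fits
are bit-reproducible. n_components defaults to N, the maximum the kernel
map supports.

## GBDT

Friedman's multiclass algorithm (softmax deviance, K trees per round,
one-step Newton leaf values) — the natural instantiation for a 4-class
task. min_samples_leaf defaults to 1 and no subsampling is used. Candidate
features are drawn uniformly without replacement per *node* (the common
reading of max_features), consumed in depth-first order from one seeded
generator for determinism; thresholds sit at midpoints of consecutive
distinct sorted values and ties break to the lowest (feature index,
threshold). max_features is clipped to the input dimension when larger.

## Evaluation

Folds are stratified by default (the class design is imbalanced-friendly;
stratification stabilises per-class recall at these sample sizes) via a
seeded shuffled splitter. "Overall accuracy" is pooled over folds — every
held-out sample counted once — with the mean of fold accuracies also
reported. The permutation null re-runs the identical pipeline on
label-shuffled copies; with 4 balanced classes it should sit at 25%.

## Problem sizes

The default study is 8 synthetic participants × 4 emotions × 5 segments of
20 s (160 segments, ~90 min of 4-channel signal), chosen so a full
strict-mode 10-fold run with 200 boosting rounds completes in a few minutes
on one CPU while keeping ≥ 14 training segments per class per fold. The
oracle suites use 10–20-point datasets (kernel PCA) and ≤ 8-sample inputs
(tree splits), where exhaustive enumeration is exact.

## Known limitations

* The detector assumes positive-going R/pulse peaks (polarity flag
  otherwise); no arrhythmia or multi-lead handling.
* LMS cancellation assumes the interference is a linear FIR function of
  the reference channel.
* Kernel PCA stores the training matrix; transform cost grows with N.
* The GBDT has no early stopping or leaf regularisation beyond shrinkage.
* Synthetic-data realism limits noted above: results quantify pipeline
  correctness, not expected accuracy on recorded humans.
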