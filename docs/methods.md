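# Methods

`whistlekit` detects bottlenose-dolphin whistles in underwater recordings by
classifying grayscale spectrogram images with convolutional networks. This
note documents the processing model, the synthetic scenes used to exercise
it, the numerical choices, and what the desk-scale results do and do not
show.

## Signal chain

**Conditioning.** Recordings (nominally 2-channel, 96 kHz) are averaged
across channels to suppress uncorrelated noise, bandpassed to 5–20 kHz with
a 4th-order Butterworth applied forward–backward (`sosfiltfilt`), and
optionally whitened by inverse-gain equalization against a supplied
instrument response curve. Zero-phase filtering was chosen so annotated
whistle onsets stay aligned with the filtered audio; the whitening default
is identity because calibration curves are instrument-specific. Bandpass is
applied before whitening. Wavelet shrinkage (Daubechies-4, 5 levels,
soft thresholding at the universal threshold σ√(2 ln N) with the MAD noise
estimate) suppresses impulsive transients; shrinkage cannot add energy, so
the denoised clip never gains power. Clipped samples are flagged at
|x| ≥ 0.999 full scale and dead stretches at a debiased RMS below 1e-5 over
100 ms windows; flagged intervals closer than 50 ms are merged. Bias
(window mean) removal applies to the dead-stretch check — removing it
before the clipping comparison would push clipped samples below any
near-full-scale threshold.

**Duration QA.** Annotated whistle durations are screened with Tukey
fences: Q1 − 1.5·IQR and Q3 + 1.5·IQR, quartiles by the linear-interpolation
convention. On real dolphin corpora this rejects sub-0.1 s fragments and
multi-second artifacts; the exact fences are data-dependent.

**Spectrogram images.** Audio is cut into 0.8 s segments advancing by
0.4 s (0.8 s covers the longest retained whistle). Each segment is
transformed with a 2048-point periodic Blackman window advancing by
hop = round(0.8 × 2048) = 1638 samples — i.e. 20 % overlap; the window
*advances* by 0.8 of its length. Power spectral density is expressed in
dB (10·log10, floored at −120 dB), cropped to 3–20 kHz, and stretched to
[0, 1] by each image's own min–max (what a default colormap rendering
does); a constant image maps to uniform 0.5. The raster is resized to
224 × 224 by bilinear interpolation and replicated across 3 identical
channels. Intensities are already in [0, 1]; no further normalization is
applied.

**Segment labels.** A segment is a whistle example iff its interval
overlaps at least 5 % of some annotated whistle's interval, the fraction
measured against the *annotation's* duration. The same 5 % rule scores
event-level detections: a truth whistle is a TP if any detected interval
overlaps ≥ 5 % of it, else an FN; detections validating no whistle are
FPs; one detection may validate several overlapping truths (a documented
choice — the alternative, one-to-one matching, changes counts only when
detections span multiple whistles).

## Detectors

Two architectures share a train/predict contract:

- **Compact CNN** — conv(16, 7×7, stride 2) → pool(2) → dropout(0.2) →
  conv(32, 5×5, stride 2) → pool(2) → dropout(0.2) → flatten →
  dense(32) → dense(16) → softmax(2), ReLU on hidden layers,
  unpadded convolutions, Adam at 1e-4.
- **Transfer model** — a VGG16 feature extractor whose classification top
  is replaced by dense(50) → dense(20) → softmax(2), all layers
  trainable, Adam at 1e-5. Pretrained ImageNet weights require a
  download, so offline builds start from random initialization; a small
  random "tiny" backbone is provided for fast tests.

The loss is cross-entropy over the 2-way softmax (the binary
cross-entropy of the positive-class probability written over one-hot
targets). Early stopping watches validation loss with patience 15 and
restores the best weights. Training, initialization (He-normal), batch
shuffling and dropout all derive from one seed, so runs are bitwise
reproducible.

The layers run on an in-package numpy engine (im2col convolution with
BLAS matmuls, float32 throughout, manually derived backward passes,
Adam). Its gradient passes are verified against numerical
differentiation in the test suite.

Hyperparameter bounds (2–4 conv layers, 1–3 dense layers, lr 1e-5–1e-2,
5–100 dense units, 8–256 filters, 3×3–7×7 kernels, patience 5–20,
dropout 0.1–0.3) are documented in `HYPERPARAMETER_SEARCH_RANGES` for
external tuning tools; no search engine is shipped.

## Evaluation protocol

Stratified 5-fold cross-validation (own implementation: per-class
shuffle, round-robin deal, per-fold class counts within one item of
proportional; cross-checked against scikit-learn's `StratifiedKFold` in
tests) yields per-fold accuracies; the final model is trained on all
training data with an internal validation split for early stopping
only. Metrics follow the standard definitions — precision TP/(TP+FP),
recall = TPR = TP/(TP+FN), FPR = FP/(FP+TN) — with zero-denominator
ratios reported as missing (NaN), never coerced to 0; percentages are
formatted to one decimal. ROC curves come from a threshold sweep over
unique scores with ties grouped, so the trapezoidal AUC equals the
Mann–Whitney concordance probability (half credit for ties); the suite
checks this identity against an O(n²) oracle and scikit-learn.

Contour QA: a hand-drawn (or synthetic) whistle contour passes if all
its frequencies lie in 3–20 kHz and the variance of spectrogram dB
values sampled at nearest bins along the contour stays below a limit
(default 25 dB²) — a genuine whistle has stable intensity along its
ridge.

## Synthetic scenes

The simulator emulates what a moored hydrophone records near a dolphin
reef, with exact ground truth:

- **Whistles**: tonal FM sweeps with parametric contours (linear,
  quadratic, sinusoidal-FM, concave-arc), durations drawn from
  [0.14, 0.78] s, fundamentals within 3–20 kHz, optional harmonics 6 dB
  down per step, 10 ms raised-cosine ramps, rendered by
  phase-integrated synthesis.
- **Noise**: Gaussian background FFT-shaped to −5 dB/octave (a
  reasonable ambient slope in the whistle band), Poisson-timed 1 ms
  exponential-decay broadband transients (snapping shrimp/clicks,
  default 1 event/s, 10–20 dB above background), optional steady ship
  tonals, overall level −30 dB re full scale.
- **SNR**: each whistle is scaled so its in-band (3–20 kHz) RMS over the
  event interval exceeds the noise's in-band RMS over that interval by
  the requested dB — the package's calibration convention, exact by
  construction and verified to < 1 dB mean absolute error in tests.

Scenes default to 5 s. Everything derives from one seed and is bitwise
reproducible.

What the simulator does *not* capture: propagation effects (multipath,
absorption), species-faithful whistle repertoires, overlapping animal
choruses, non-stationary sea states, and recorder artifacts beyond
clipping. Passing desk-scale tests therefore demonstrates the pipeline
and the architectures' ability to learn curving time-frequency ridges in
structured noise — not field performance on sea recordings.

## Desk-scale learning runs

The repository's checks train the compact CNN on synthetic corpora small
enough for one CPU: 400 training segments at ≥ 20 dB SNR (10 epochs) and
an independent 600-segment test set at 10–25 dB, plus a 3-seed
comparison of test AUC between easy (15–25 dB) and hard (0–10 dB)
noise bands at reduced size. For these small corpora training uses
batch size 2: a field-scale corpus (~10⁵ images) supplies thousands
of optimizer steps per epoch at batch 32, while 400 images supply only
13; shrinking the batch restores enough Adam steps for the 1e-4
learning rate to converge within the run's epoch budget, without
touching the architecture, loss, or learning rate. Batch size remains
configurable (default 32) for larger corpora. The cross-validation
harness is exercised on a compact separable task rather than the full
image problem to keep the suite fast.

## Numerical choices and degenerate inputs

- dB floor −120 dB avoids log(0); all-zero segments render as uniform
  0.5 gray.
- Per-image min–max scaling guards the constant-image case (→ 0.5).
- Max-pool gradients split equally among tied maxima, conserving the
  gradient sum.
- Tukey fences require ≥ 4 whistle annotations; quantiles interpolate
  linearly between order statistics.
- ROC requires both classes present; undefined metric ratios are NaN.
- Intervals are half-open `[t0, t1)` in seconds from recording start.
- Seeds: every stochastic component (scene synthesis, shuffling, weight
  init, dropout) receives a seed derived from the global one.

## Known limitations

- No FLAC decoder is bundled; convert FLAC archives to WAV upstream.
- The transfer model cannot load pretrained ImageNet weights offline, so
  its headline advantage (transfer learning) is only exercised
  architecturally, not with pretrained features.
- The numpy engine is single-threaded BLAS-bound; it is meant for
  desk-scale experiments, not for training on field-scale corpora.
- Event-level scoring has no TN notion, so accuracy/FPR are undefined
  there (reported as missing).
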