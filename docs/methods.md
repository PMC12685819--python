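# Methods

`affectsense` implements a dual framework for affect recognition from
wearable biosignals: (i) a 1-D convolutional classifier for discrete stress
states on heart-rate-variability (HRV) feature tables, reused via transfer
learning for activity recognition, and (ii) a Temporal Conformer regressor
for continuous valence–arousal–dominance (VAD) prediction from ECG, followed
by rule-based affective diagnostics. This note records the models, the
conventions that make every number reproducible, and the choices made where
the design was genuinely open.

## The neural-network engine

No deep-learning framework is used: both architectures, their losses and the
training loop are implemented directly in numpy (`affectsense.nn`) with
hand-derived backward passes. This keeps the dependency surface small and
every gradient inspectable; all backward passes are verified against central
finite differences (absolute tolerance ~2e-7) in the test suite. Adam is the
only optimiser (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Tensors are channels-last:
(batch, length, channels).

### 1-D CNN stress classifier

Layer order: Conv1D(64, kernel 3, ReLU, L2) → BatchNorm → MaxPool(2) →
Dropout(0.4) → Conv1D(128, kernel 3, ReLU, L2) → BatchNorm → MaxPool(2) →
Dropout(0.4) → GlobalAveragePooling → Dense(64, ReLU) → Dropout(0.4) →
Dense(k, softmax). A 62-feature HRV row is consumed as a length-62,
single-channel sequence. Choices the architecture description leaves open,
fixed here: same-padding and stride 1 for convolutions, pool size 2, L2
coefficient 1e-4, Glorot-uniform initialisation (seeded).

Training: Adam at 1e-3 (1e-4 when fine-tuning), batch 128, at most 50
epochs, sparse categorical cross-entropy (or focal loss, γ = 2) with
balanced class weights w_c = n/(k·n_c). Early stopping (patience 8) restores
the best-validation-loss weights; reduce-on-plateau halves the learning rate
after 4 non-improving epochs down to 1e-6. The patience values are this
package's defaults — the source architecture states the callbacks but not
their patience.

Transfer learning loads every backbone weight (both conv blocks, batch-norm
statistics, and the dense embedding) from the checkpoint bitwise, rebuilds
the softmax head for the new label set, and trains everything at the reduced
rate; a flag freezes the convolutional blocks instead. Nothing is frozen by
default.

### Temporal Conformer VAD regressor

Input is the 33-value feature vector of one ECG window, treated as a
length-33, single-channel sequence: Conv1D(32, ReLU) → Dropout →
Conv1D(64, ReLU) → Dropout → position-wise dense projection to d = 64 →
2 transformer encoder blocks (4 heads, FFN width 128, post-norm residuals,
dropout, attention weights retained for inspection) → LayerNorm → Dropout →
flatten → Dense(3). Trained with smooth-L1 (β = 1) and the same plateau
scheduler. The "flatten → project → reshape" step in the source description
is realised as a position-wise projection — algebraically the same map
applied per position — because the attention tensors are specified as
33 × 33. No positional encoding is added: the description never mentions
one, and the convolutional front-end already encodes locality. Depth, head
count and dimensions are configurable; the defaults above are deliberately
small.

## Feature extraction (33 per window)

Each 5 s, 640-sample ECG window yields, in fixed order:

* 11 statistical — mean, median, SD, IQR, skewness, excess kurtosis, min,
  max, range, RMS, Shannon entropy. Population moments; skewness m₃/m₂^1.5
  and Fisher kurtosis m₄/m₂² − 3, both 0 on constant input; percentiles with
  linear interpolation; entropy from a 16-bin equal-width histogram over the
  window's own [min, max], log base 2, 0·log 0 := 0. The source names ten
  statistical quantities but counts eleven; the eleventh here is the range
  (max − min), consistent with its "range-based metrics" grouping. This is a
  reconstruction, not an authorial definition.
* 12 wavelet — db4 decomposition to level 3 with symmetric boundary
  extension; mean, SD and RMS energy per sub-band in the order A3, D3, D2,
  D1.
* 10 spectral — mean power (squared magnitude; a flag switches to
  magnitude) of the 10 lowest bins of an STFT with a 64-sample Hann window
  and hop 32, no boundary padding.

Every feature is checked against an independent naive-loop oracle (explicit
Python sums, direct DFT, direct convolve-and-downsample wavelet steps) to
1e-9 on random segments.

## Preprocessing conventions

* Z-scoring uses population SD (divide by n), the standard-scaler
  convention. Table-wise statistics are fit on training data only; the ECG
  path standardises each trace individually before windowing.
* The 70/15/15 split takes floor(0.70·n) rows for training, then gives
  validation the floor of half the remainder and test the rest — so
  135,650 rows split as 94,955 / 20,347 / 20,348. Stratification allocates
  per class by largest remainder, keeping proportions within one row per
  class per part.
* Windows are half-open [start, start + W), starting at 0, S, 2S, …, with
  the incomplete tail dropped: floor((N − W)/S) + 1 windows. Each window
  inherits its parent trial's label triple, with subject/trial provenance.
* SAM ratings map from the 1–5 scale to [0, 1] by (x − 1)/4.
* Filtering (Butterworth band-pass order 4, IIR notch Q = 30) is zero-phase
  (forward–backward) and off by default; the HRV-table path needs none.

## Synthetic data: what it emulates, and what it does not

The generators stand in for the three study datasets so every stage is
trainable and testable without downloads. They are statistical emulations,
not physiological simulations.

* Stress table: 62 features, 3 classes with proportions
  (0.5281, 0.1700, 0.3019), class-conditional Gaussians mean-shifted by a
  configurable effect size on a random half of the features. Class counts
  round to the proportions with the remainder assigned to the largest class.
* ECG: Gaussian-shaped P/R/T complexes (R width σ = 0.02 s, unit amplitude;
  P 0.15 at −0.15 s, σ = 0.04 s; T 0.50 at +0.30 s, σ = 0.06 s), first R
  peak fixed at 0.5 s, RR intervals Normal(60/HR, rr_sd) truncated positive,
  0.2 Hz baseline wander, white noise. Two physiological couplings make the
  latent parameters observable in 5 s windows: beat amplitude is modulated
  by the relative RR deviation, and a 0.25 Hz respiratory baseline component
  has depth proportional to rr_sd — both stand-ins for respiratory sinus
  arrhythmia, whose vagal driver produces correlated timing and amplitude
  modulation in real ECG. Without them the fixed 33-feature set cannot see
  heart rate or RR variability at all (verified with a gradient-boosting
  oracle during design), which would contradict the generator's purpose of
  providing a recoverable latent→label map.
* Latent ranges (heart rate 55–110 bpm; RR SD 0.02–0.12 s, the realistic
  SDNN range; noise SD 0.05–0.40 of R amplitude) are drawn uniformly per
  trial. The default label map is affine and clipped to [1, 5]: arousal
  rises with heart rate, valence falls with noise, dominance falls with RR
  variability — giving each output an independently recoverable signal.
  Label jitter defaults to 0, making labels an exact function of latents.
* Activity windows: 4 classes with the study's 12137 : 969 : 699 : 131
  imbalance (~93:1 extremes), each class a distinct dominant sinusoid
  frequency/amplitude over unit noise, scaled by an effect size.

What passing tests therefore show: the pipelines can extract planted,
physiologically-plausible structure under class imbalance and label-inherited
windowing. What they do not show: performance on real recordings, with real
inter-subject variability, artefacts, and far weaker latent–label coupling.

## Evaluation protocol and a leakage caveat

The VAD pipeline follows the study protocol: trials are windowed with 50%
overlap, windows inherit trial labels, and the train/validation/test split is
taken at the *window* level. Windows of one trial therefore appear on both
sides of the split, and the held-out R² partly reflects trial
re-identification rather than pure latent recovery — a known weakness of
segment-level splitting in this literature. A stricter trial-grouped split is
available (`run_vad_pipeline(split_by_trial=True)`); it yields lower scores,
dominated by the per-window information ceiling for RR variability.

Metrics: MAE and RMSE pool over all n×3 errors; R² is computed per dimension
and averaged; rounded accuracy maps predictions and targets back to the 1–5
scale (x·4 + 1) and compares integers after rounding half away from zero,
per dimension and jointly. For classification, the report is computed from
the confusion matrix (precision by column, recall by row, harmonic-mean F1,
macro and support-weighted averages); weighted recall equals accuracy by
construction, which the tests assert as an identity.

## Diagnostics

States are assigned by the first matching rule in the precedence
Happy/Excited → Stressed → Relaxed → Fatigued → Passive → Neutral, with
inclusive min/max thresholds and strict "below" thresholds. Defaults:
Happy (arousal ≥ 0.6, valence ≥ 0.7); Stressed (arousal ≥ 0.6,
valence ≤ 0.4); Relaxed (arousal ≤ 0.3, valence ≥ 0.7); Fatigued
(arousal ≤ 0.3, valence ≤ 0.3); Passive (arousal < 0.4, dominance < 0.5).
The published account gives the rule structure but not the numbers; these
thresholds are a reconstruction that reproduces all ten published example
states, and any consistent alternative can be configured. Fatigue Index is
1 − arousal; Motion Quality is valence × dominance; k-means (k = 4,
k-means++ with 10 restarts, seeded) profiles the predicted VAD space.
Display tables round half away from zero to 2 decimals. One caveat: the
published example table computed its index columns from unrounded
predictions, so recomputing Motion Quality from the printed 2-decimal VAD
values lands one display ulp away on two of the ten rows; no rounding rule
can reproduce both of those rows from the printed inputs.

## Explainability

Grad-CAM weights each filter of a chosen convolutional layer by the
time-averaged gradient of the target logit, rectifies the weighted sum,
linearly upsamples to input length and min–max normalises; an identically
zero map (observed in practice when transferred models attend to global
statistics) is returned as zeros rather than an error. The multichannel
variant distributes the shared time profile across input channels in
proportion to each channel's share of input-gradient magnitude, then
normalises jointly (per-channel normalisation available); it reduces exactly
to the single-channel map for one channel. Integrated Gradients uses a
midpoint Riemann grid from a zero baseline in the model's standardised input
space and reports the completeness gap Σ IG − (F(x) − F(baseline)).
Limitation: for layer-norm networks the zero baseline sits at a
scale-invariance singularity, concentrating the path integral's mass near
the baseline and breaking completeness; use a small non-degenerate baseline
(e.g. noise) for the conformer. t-SNE (perplexity 30, seeded, PCA
initialisation) projects the CNN's pooled embeddings.

## Numerical and degenerate-input conventions

EDF is written as 16-bit with one data record per second (integer rates,
whole seconds; round-trip exact to one quantisation step); blank physical
dimension keeps values unscaled. The DREAMER-style MAT reader unwraps
arbitrarily nested 1×1 object arrays and takes the first ECG lead (flag to
average). Checkpoints are npz archives of named arrays plus a versioned JSON
descriptor; loading validates every shape. Entropy of a constant (or
sub-resolution) window is 0; skewness/kurtosis of a constant window are 0;
z-scoring rejects constant features; k-means requires n ≥ k; R² raises on a
constant target dimension instead of returning a misleading value.

## Problem sizes

Default study sizes for the runnable pipelines were chosen so a complete
run (all three pipelines) finishes in minutes on one CPU core: 3,000-row
stress tables, 2,000 activity windows of 250 samples, and 16 × 12 trials of
61.25 s for the VAD path (4,416 windows). All sizes are parameters; the
structural tests additionally exercise the full 135,650-row split
arithmetic and the 23 × 18 trial-count convention directly.
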