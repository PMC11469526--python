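# Methods

This note documents the models implemented by `eswcnn`, the conventions and
numerical choices they rely on, and what the synthetic benchmarks do and do
not demonstrate.

## Windowed scattering transform

The fixed feature extractor is the 2-D windowed scattering transform: a
cascade of complex wavelet convolutions, pointwise modulus, and a final
Gaussian low-pass,

    S[p]x = | ... | |x * psi_{l1}| * psi_{l2}| ... | * phi_{2^J},

indexed by paths `p = (l1, ..., lm)` of scale/orientation pairs
`l = (j, theta)`. Order-0 is plain local averaging; order-1 captures
oriented band energy; order-2 captures interactions between bands. Paths
obey the frequency-decreasing rule `j2 > j1` — other second-order paths
carry negligible energy and are omitted, giving
`1 + J*L + L^2 * J(J-1)/2` coefficient maps per input channel.

**Filters.** Morlet wavelets built in the spatial domain on the periodized
grid (3x3 shift sum) and transferred to the FFT grid, with

* envelope width `sigma = 0.48 * 2^j` pixels,
* center frequency `xi = 3*pi/4 / 2^j` rad/pixel,
* anisotropy `slant = 5.5 / L`,
* orientations `theta = pi*t/L, t = 0..L-1`,
* Gaussian low-pass with `sigma_phi = 0.65 * 0.48 * 2^J`, unit DC gain.

These widths are deliberately broader than the classical ScatNet choice
(`sigma0 = 0.8`, `slant = 4/L`). On a 28x28 grid the classical filters
leave deep gaps in the Littlewood–Paley sum (it dips to ~0.4 for J=1 and
~0.04 for J=2 at 8 orientations), i.e. whole frequency bands are nearly
invisible to the transform. Each band-pass filter is normalized to unit
peak gain, the family is then globally rescaled so the Littlewood–Paley sum

    |phi_hat(w)|^2 + 1/2 * sum_l (|psi_hat_l(w)|^2 + |psi_hat_l(-w)|^2)

never exceeds 1 (the transform is energy non-expansive), and with the
widened parameterization it stays above `1 - eps` with `eps = 0.2` over the
Nyquist disc `0 < |w| <= pi` for the default 8-orientation banks. The bound
is stated over the Nyquist disc because the corners of a square frequency
grid lie beyond the isotropic Nyquist radius; no oriented wavelet family
covers them, and band-limited images carry no energy there. Banks with few
orientations (L <= 4) are necessarily looser frames; every bank stores its
measured `eps`, and the zero-mean correction makes `psi_hat(0) = 0` exact.

**Sampling.** Convolutions are circular (periodic boundary) via the FFT; on
28x28 inputs no reflection padding is used, which keeps the implementation
exactly equal to a direct spatial-domain oracle (tested to 1e-6).
Coefficients are critically subsampled at stride `2^J` after the low-pass.
For depth-concatenation with raw channels, maps are nearest-neighbor
upsampled back to the input grid. Path order is lexicographic in
`(order, j1, t1, j2, t2)` and fixed, so exported feature stacks and saved
models are portable.

## Hybrid layers

**Scattering-concatenation convolution.** Raw channels and their scattering
maps are concatenated along depth and passed through a shared 3x3
convolution with stride 2 and 1-pixel zero padding, bias and ReLU (the
activation is a configuration choice; ReLU is the default). A 28x28 input
therefore maps to 14x14. With the scattering stack zeroed, the layer is an
ordinary convolution — that zeroed variant is the parameter-matched plain
CNN baseline used in the ablation.

**Discriminant frequency filter.** A residual layer with a learnable
complex weight map `W`:

    F_out = F + Re( IFFT( W ∘ FFT(F) ) ),

with the unnormalized forward DFT and `1/(H*W)` inverse. Under this
convention a weight `w` on the DC bin maps a constant input `c` to
`c * (1 + Re w)`. The real part is taken after the inverse transform
(equivalent to Hermitian-symmetrizing `W`), and `W` is initialized to zero
so the layer is exactly the identity at the start of training — training
starts from a known-safe operating point. The layer is linear in its input;
its gradients follow from the DFT adjoint and are finite-difference checked.
It is optional and off by default in the image model, and on by default (as
a 1-D variant along time) in the signal pipeline, mirroring where the
ablation study places it.

## Reference architecture and training

The image classifier is a depth-7 network for 28x28x3 inputs:

| stage | operation | output |
|---|---|---|
| 1 | scatter-concat conv (J=1, L=8, order 1; depth 3+27 -> 32) | 32 x 14 x 14 |
| 2 | 3x3 conv, stride 2 (32 -> 48) | 48 x 7 x 7 |
| 3 | 3x3 conv, stride 2 (48 -> 64) | 64 x 4 x 4 |
| 4 | global average pool | 64 |
| 5 | dropout 0.2 | 64 |
| 6 | linear -> softmax (CNN head) | n_classes |
| 7 | auxiliary head: pooled order-2 scattering (J=2, L=8; 243 features) -> linear -> softmax | n_classes |

Stage widths (32, 48, 64) were chosen to fit the 60k-parameter budget:
8,672 + 13,872 + 27,712 + 195 + 732 = 51,183 trainable parameters
(0.0512 M), enforced programmatically at build time. A configuration flag
(`scatter_every_stage`) re-concatenates scattering maps of the intermediate
feature maps before every convolution for the deeper hybrid variant; it is
off in the reference model.

**Dual-head loss.** With one-hot label `y` and softmax outputs `yhat(x)`
(CNN head) and `yhat(S[x])` (scattering head),

    L = ||y - yhat(x)||^2 + gamma * ||y - yhat(S[x])||^2,

batch-averaged; `gamma in [0, 1]`, default 0.5. A cross-entropy variant of
both terms is selectable by flag. Optimization is SGD with momentum 0.9
(learning rate 3e-4, batch 10, 6 epochs, every-epoch shuffling, dropout
0.2); all randomness (init, shuffling, dropout) derives from the config
seed, so runs are bitwise reproducible.

Because the scattering head is a single linear layer on *fixed* pooled
coefficients, it shares no parameters with the CNN trunk; `gamma`
therefore scales only the scattering head's gradient. Two consequences,
both verified by tests: the CNN head's trajectory is identical for any
`gamma`, so the `gamma = 0.5` arm is never worse than `gamma = 0`
(they tie exactly on that head); and at `gamma = 0` the scattering head
stays at its random initialization while at `gamma = 0.5` it reaches
near-oracle accuracy. A design in which the heads shared trunk parameters
would let `gamma` regularize the trunk; with the fixed-feature head adopted
here the auxiliary branch instead provides an independent, globally
translation-invariant prediction at negligible parameter cost.

The pooled auxiliary features are standardized (per-feature mean/sd fitted
on the training set, stored with the checkpoint). Raw scattering
coefficients span two orders of magnitude across paths; without
standardization the linear head barely moves at the prescribed learning
rate within 6 epochs.

**Prediction.** The reported label is the argmax of the CNN head; exact
ties resolve to the lowest class index.

## Evaluation conventions

Confusion matrices store predicted classes in rows and actual classes in
columns (column sums = class sample counts). For >= 3 classes all metrics
are one-vs-rest per class; both the micro average (trace/total) and the
macro average (mean of per-class one-vs-rest accuracies) are reported
because "average accuracy" is ambiguous between them. A metric whose
denominator is zero is reported as NaN with an `undefined` flag, never
silently as 0 or 1; F1 is defined as 0 only in the precision+recall = 0
case where both are themselves defined.

n-fold splits are stratified by default (per-class round-robin dealing of
shuffled indices, keeping class proportions within one sample per fold; a
class smaller than n triggers a logged fall-back to unstratified). The test
fraction `p = #test/#all = 1/n` up to rounding. Cross-validation trains a
fresh model per fold with seed `master_seed + fold_index` and aggregates
per-class accuracy as mean ± std. ROC curves use a stable descending score
sort with tied scores merged into single threshold steps and trapezoid-rule
AUC; one-class inputs yield an explicit undefined AUC.

## Synthetic benchmarks

**Textures.** Each class is an oriented band-pass Gaussian random field:
white noise shaped in frequency by a radial band (cycles/pixel) and a
Gaussian angular lobe, mixed with a small broadband component
(band-energy ratio 0.85), scaled into [0, 1], replicated to 3 channels,
multiplied by a per-image illumination gain drawn from [0.6, 1.4] and
perturbed by pixel noise (sigma 0.04). Classes differ exactly in spectral
orientation/scale content — the property scattering features discriminate —
while the illumination jitter emulates the lighting variation that
handicaps raw-pixel classifiers. The default 3-class benchmark uses 400
images per class (1,200 total); the 2-class benchmark 300 per class. These
fields are stationary Gaussian textures: they have no lesion geometry,
specular highlights, vignetting or spatial nonstationarity, so passing
benchmarks demonstrates that the architecture exploits spectral structure
under illumination jitter, not clinical-grade polyp discrimination.

**Signals.** Sums of sinusoids with class-dependent peaks inside 1–10 Hz
(class "negative": 2 and 5 Hz; "positive": 3.5 and 8 Hz; amplitudes
1.0/0.7), random phases, white noise sigma 1.0, sampled at 50 Hz for
2.56 s (128 samples), 200 sequences per class. A fixed periodogram
band-energy rule separates the default classes at >= 95%, which pins the
benchmark's achievable accuracy; real weak-magnetic recordings would add
drift, line interference and inter-subject variability that these
stationary sinusoids do not model.

All generators are pure functions of (spec, n, seed). Benchmark sizes were
chosen so a full train-plus-evaluation pass of every ablation arm completes
in a few minutes on one CPU core.

## Signal pipeline

Stages, in order: feature expansion → three-selector vote → t-test screen →
PCA → LSTM.

* **Expansion**: per signal, (mean, std, energy, Shannon entropy of the
  normalized squared coefficients) of the raw samples and of the cA/cD
  sub-bands of a single-level DWT for the families cdf9/7 (the 9/7-tap
  biorthogonal pair, `bior4.4` in PyWavelets), bior3.9, sym5 and db4, plus
  FFT magnitude-band energies over nine 1-Hz bands spanning 1–10 Hz:
  4 + 4*8 + 9 = 45 named columns by default. DWT uses periodization mode so
  orthogonal families conserve energy exactly (Parseval-tested).
  Decomposition depth is configurable; one level is the default.
* **Vote**: method A keeps the top 30 features by seeded random-forest
  importance; methods B and C keep the top fraction q = 0.99 (i.e. discard
  the worst 1%) by absolute Pearson correlation with the label and by
  variance of the per-feature softmax-normalized column respectively. A
  constant column has zero correlation and softmaxes to uniform (zero
  variance), so it is discarded first by both. Features with >= 2 of 3
  votes survive; the threshold is configurable (intersection = 3).
* **Screen**: Welch's two-sample t-test (two-sided, unequal variances) per
  feature; features ranked by ascending p. The standalone screen defaults
  to the top 1%, appropriate for tables with thousands of columns; the
  desk-scale pipeline keeps the top 25% because its table has ~10^2
  columns and a 1% screen would leave a single feature.
* **PCA**: features are z-scored, reduced to at most 12 components
  (bounded by the data rank), scores variance-normalized.
* **LSTM**: the component scores are read as a length-k sequence of
  scalars (leading components first) by a 16-unit LSTM (forget-gate bias
  initialized to 1), final hidden state → linear → softmax, cross-entropy,
  SGD-momentum (lr 0.05, batch 16, 30 epochs — the signal branch's own
  recipe; the image recipe's 3e-4 x 6 epochs is far too short for
  recurrent training). A learnable 1-D residual frequency filter on the
  input sequence (zero-initialized, identity at start) is enabled by
  default. Sequences of unequal length are truncated to the shortest,
  never padded.

The raw-sequence LSTM baseline reads the standardized 128-sample signal
directly with the same classifier settings.

## Numerical choices and degenerate inputs

* FFT normalization: unnormalized forward, `1/N` inverse, everywhere.
* Gradients of every hand-written layer (convolution, spectral filters,
  LSTM) are validated against central finite differences (rel. err <= 1e-4
  at step 1e-5 or 1e-6 for the LSTM's longer chains).
* Prediction ties: lowest class index. ROC tie handling: stable sort,
  merged thresholds.
* Degenerate metric denominators: flagged NaN (see above). Empty datasets,
  missing classes, single-class training sets, shape mismatches and
  out-of-range hyperparameters raise informative errors rather than
  propagating garbage.
* Scattering order is capped at 2: third-order coefficients carry little
  energy (the order-2 <= order-1 energy ordering is property-tested) at
  cubic path-count cost.

## Known limitations

* Periodic boundary handling wraps image content; for 28x28 thumbnails the
  effect is negligible, but for large images reflection padding would be
  preferable to avoid edge artifacts.
* The parameter-matched plain-CNN baseline zeroes the scattering stack
  rather than removing those kernel slices, so its effective capacity is
  slightly below its parameter count.
* The gamma ablation cannot show a trunk-regularization effect by
  construction (see the dual-head loss section).
* Training is single-device, pure NumPy; it is fast at the 28x28 /
  60k-parameter scale this package targets but does not vectorize across
  devices or use GPUs.
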