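# Methods

## The measurement model

One acquisition consists of eight spectra on a uniform wavelength grid:
rows 1–7 are emission spectra recorded while LEDs 1–7 (Gaussian lines
centred at 371, 381, 394, 404, 412, 423, 431 nm, default FWHM 15 nm) are lit
in sequence, row 8 is a dark background. The grid spans 200–1100 nm and is
aligned so that the closed analysis window [500, 900] nm contains exactly
837 samples, which fixes the step at 400/836 ≈ 0.4785 nm; 500 and 900 nm
then fall exactly on grid points. The 15 nm LED width keeps every LED's
Gaussian wing below 10⁻⁴ of peak at 500 nm, so excitation light never
contaminates the fluorescence window.

Leaf fluorescence is a sum of three Gaussian bands (amplitudes in units of
the red chlorophyll peak):

| band | centre (per class) | σ (nm) | role |
|---|---|---|---|
| green-orange | 545–560 nm | 35 | UV-A-excited band of mixed origin |
| chlorophyll red | 677.5–682 nm | 10 | normalization reference (amplitude 1) |
| chlorophyll far-red | 735–745.5 nm | 16 | fermentation marker |

Row *r* of a measurement is
`background(λ) + reflection·LEDᵣ(λ) + Σ_b A_b · eff_b(r) · exp(−(λ−c_b−δ)²/2(σ_b s_b)²)`
plus additive Gaussian detector noise (σ = 1% of the red peak), clipped at
zero counts; row 8 is background plus noise. The background is a smooth
low-amplitude quadratic (5% of the red peak). Per measurement, one
amplitude `A_b` is drawn per band (lognormal, preserving positivity), one
wavelength jitter `δ` (Gaussian, σ = 2 nm) shifts all band centres
together, and one width scale `s_b` per band (lognormal, CV 5%) — all
shared across the seven LED rows, because the leaf does not change between
the sequential exposures. Excitation efficiency `eff_b(r)` is a Gaussian in
the distance between the LED centre and the band's absorption optimum: a
narrow UV-A optimum (371 nm, σ = 5 nm) for the green-orange band, so only
LED1 excites it appreciably, and a broad Soret optimum (422–437 nm by
class, σ = 45 nm) for both chlorophyll bands, so all seven LEDs excite
them.

### Class calibration

The nine classes differ in: far-red/red amplitude ratio (0.66–0.82 for the
six green classes, 0.68 for the white tea, 0.42 and 0.55 for the two black
teas — the fermentation-grade split at 0.6, with G-HM (0.66) and B-L (0.55)
deliberately close enough to overlap given the 15% amplitude CV);
green-orange amplitude (G-LJ2 clearly highest at 0.55, then G-LJ1, G-LJ3
and B-KM at 0.32–0.38, the rest ≤ 0.18); band centres; Soret optimum; and a
far-red *excitation tilt* (±15% linear change of the far-red efficiency
from LED1 to LED7, a reabsorption effect of excitation depth). The split
threshold is checked on the post-preprocessing normalized far-red
amplitude, which is what the ratio approximates after per-row
normalization.

Two structural choices make the generator reproduce the qualitative gap
between the classifier families rather than merely their absolute
accuracies. First, the dominant within-class variation (amplitude CVs,
shared jitter) lies along directions common to many classes, so the top
principal components are spent on nuisance; with the small per-LED PC
budgets, PCA+kNN plateaus around 0.8. Second, a large part of the class
identity is carried by *jitter-free relational* features — the red-to-
far-red peak spacing (unique per class, spacings ≥ 1.5 nm apart, whereas
the shared jitter moves both peaks together) and the far-red excitation
tilt across LEDs (the shared amplitude draw cancels in cross-row
contrasts). These are invisible to distance-based classification on a few
unsupervised components but learnable by a discriminatively trained
network, so the achievable accuracy is near 1 while the baselines err.

A single `overlap` dial multiplies all three nuisance scales (amplitude CV
0.15, jitter 2 nm, width CV 0.05 at `overlap=1`). `overlap=0` gives
essentially deterministic class templates (every classifier ≥ 0.99);
`overlap=1` is the committed calibrated regime (best baseline ≈ 0.81, CNN
≈ 0.985). The magnitude of real measurement fluctuation is not published
for this kind of instrument, so the CVs are surfaced in the profiles and
the dial rather than hard-coded.

## Pre-processing

Order matters and is fixed: background subtraction → Savitzky–Golay
smoothing (2nd order, default window 11 points ≈ 5.3 nm: wide enough to
suppress the 1%-level detector noise, narrow against the ≥ 23 nm FWHM
bands) → per-row normalization to the maximum in 650–700 nm → truncation
to the 837-point window. Normalizing before smoothing would leave the
red-region maximum below 1. Normalization is per LED row (each row's red
peak becomes exactly 1); a single per-measurement factor is the main
alternative reading, but per-row matches how the single-LED spectra are
displayed and analysed independently. Smoothing edges use a one-sided
polynomial fit on the terminal window; the edges lie outside the analysis
window anyway. A row whose 650–700 nm maximum is not positive raises a
degenerate-spectrum error carrying the measurement id. The train/test
split is a seeded stratified shuffle, 50/50 by default.

## Baselines

PCA is mean-centred only — no per-feature autoscaling, since all channels
share units — with a fixed sign convention (largest-magnitude loading
element positive). kNN uses Euclidean distance and k = 5 (odd, standard
chemometrics default; k is config-exposed), with ties broken by smallest
mean neighbor distance, then lexicographic label order. The per-LED PC
counts (11, 6, 3, 3, 3, 4, 11), the 9 components of the
concatenated-spectra variant and the 41-feature concatenated-PC variant
are fixed configuration, not re-optimized. PCA is computed by
scikit-learn's exact SVD solver behind the package's own model type; the
test suite verifies it against an explicit covariance eigendecomposition,
and kNN against an exhaustive distance scan.

## The network

`conv(32 × 7×7, valid, stride 1, horizontal only) → ReLU → flatten(26592)
→ dense(128) → ReLU → dense(9) → softmax`, cross-entropy loss, plain SGD
with learning rate 0.1 and momentum 0. There is no pooling layer: a
spectral feature is an amplitude relation between exact wavelengths, so
positional down-sampling would discard signal. "Two fully connected
layers" is read as one hidden layer plus the 9-unit output layer; the
hidden width (128) and depth are config options. Weights use seeded
He-style uniform initialization; forward/backward passes are plain numpy
(float32 by default, float64 available for gradient tests), with the
convolution evaluated against sliding-window patches extracted once per
dataset since the first layer's input is constant during training.

**Balanced batches.** Minibatches are class-balanced by default: each batch
of 18 holds 2 samples of every class. At this learning rate without
momentum, the class-composition component of the gradient noise in plain
shuffled batches is large enough that training oscillates indefinitely at
desk scale (270 training matrices): across seeds, final test accuracy
varied between 0.6 and 0.94 with shuffled batches of 32, while the same
optimizer on class-balanced batches converges to a stable ≈ 0.98
(training accuracy saturates, after which the softmax margins grow and the
effective curvature dies away). Balancing requires equal class counts and
a batch size divisible by the class count, and falls back to plain
shuffling otherwise; a full-batch deterministic mode (`batch_size=None`,
no shuffling) exists for gradient and order-invariance tests. A
cross-entropy above 100 nats (softmax saturated on the wrong class) aborts
training with an error naming the learning rate as the likely cause.

## Evaluation conditions

`run_full_comparison` evaluates the seven per-LED baselines, the two fused
baselines and the CNN on one shared stratified 50/50 split, and repeats the
experiment over three seeds (data, split and initialization all derive
from the seed); ordering claims are made on the means. The committed
desk-scale conditions are 60 measurements per class and 200 training
epochs, which keep the full three-seed comparison around six minutes on
one CPU core while leaving the CNN fully converged (training accuracy 1.0
well before epoch 200). The CLI's `train-cnn` default remains 500 epochs
for single runs.

## What the generator does and does not emulate

It emulates: the sequential 7-LED + background acquisition, physically
plausible band shapes and positions, fermentation-dependent far-red ratios,
class-dependent excitation-efficiency patterns, correlated
within-measurement fluctuation, detector noise, and excitation-light
leakage below 500 nm. It does not emulate: radiometric calibration,
integration-time and saturation effects, wavelength-dependent detector
sensitivity, band asymmetry/overlapping fine structure of real leaf
fluorescence, surface/orientation effects of intact leaves, or drift
between sessions. Passing the calibrated-regime ordering test therefore
shows that the *pipeline* reproduces the qualitative mechanism (relational
EEM features reward a trained convolutional model over unsupervised
projection + distance classification); it does not certify accuracies on
any real instrument's data.

## Numerical notes and limitations

* Grid arithmetic is exact by construction (500 and 900 nm are grid
  points); window membership uses a 5·10⁻⁴ nm tolerance.
* Band centres falling exactly between two grid points make the discrete
  argmax tie between neighbours; peak-location tests accept either.
* The lognormal amplitude draws give the normalized far-red amplitude a
  small positive bias (≈ +2% at CV 0.15, the ratio of two lognormals),
  which the calibration margins absorb.
* Savitzky–Golay attenuates the 10 nm-σ red peak by well under 0.1%, so
  per-row maxima equal 1 to float tolerance after normalization.
* Training is reproducible bit-for-bit for a fixed seed, BLAS build and
  thread count; across builds only statistical reproducibility is claimed.
* With fewer than ~10 measurements per class the CNN may need more than
  200 epochs; the divergence guard and the trace make this visible.
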