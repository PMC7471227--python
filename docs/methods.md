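# Methods

`mitopo` implements an interpretable classification chain for motor-imagery
(MI) EEG: per-electrode band-power features, topographic scalp images, a
small multi-input CNN, and back-projection of the learned dense-layer
weights into scalp relevance maps that support electrode selection.  This
note records the model, its assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## Signal model and preprocessing

Trials are 7 s of 22-channel EEG at 250 Hz; the imagery interval is 3–6 s
after trial start.  The continuous record is band-pass filtered to 8–30 Hz
with a fifth-order Butterworth filter applied forward–backward
(`scipy.signal.sosfiltfilt`), so the phase response is zero and the
effective order doubles; filtering precedes epoching so filter transients
fall outside the trials.  Each trial is segmented into 2 s windows with 1 s
step.  With a 7 s trial this convention admits six windows; we keep the
five windows starting at 0…4 s (covering 0–6 s) and discard the final
second, matching the segment count N_τ = 5 and the last analysis window
[4–6] s.  A window as long as the trial is still accepted and yields one
window.

## Features

Two interchangeable extractors produce a nonnegative spectrum per channel
and window:

* **Welch PSD** — averaged modified periodograms, segment length 256
  samples, 90 % overlap, Hann taper (the taper shape is our choice; the
  "modified periodogram" convention leaves it open), `scaling="density"`.
  A 500-sample window yields M = 10 averaged segments.
* **Morlet CWT** — complex Morlet (`cmor1.5-1.0`), 16 scales whose centre
  frequencies are log-spaced over 8–30 Hz ("16" is read as the number of
  scales).  The transform is a correlation of the signal with the scaled,
  conjugated wavelet, evaluated by FFT convolution over a batched axis;
  PyWavelets supplies the wavelet samples and `pywt.cwt` serves as an
  independent cross-check in the tests.  The time-average that collapses
  coefficients to a spectrum is taken over the squared magnitude |ς|²
  (averaging the complex coefficients themselves would cancel the
  oscillatory phase and cannot yield the nonnegative spectrum the band
  accumulation needs).

Band power is the inclusive sum of spectral bins inside each rhythm: μ
[8–12] Hz, β_low [16–20], β_med [20–24], β_high [24–28]; β = [16–28] is the
union of the three sub-bands.  Adjacent printed bands share a boundary bin;
bands are processed as separate CNN branches and never summed, so the
double count is harmless.  Scenario → band sets: A = {μ}, B = {β},
C = {μ, β}, D = {μ, β_low, β_med, β_high}.  The per-(trial, window, band)
result is a length-22 electrode contribution vector ρ.

## Topographic maps

ρ is interpolated on the unit sphere with Perrin-style spherical splines
(order m = 4, Legendre series truncated at 50 terms).  The linear system
carries a tiny ridge (1e-10) purely to guard against coincident
electrodes: the m = 4 kernel Gram matrix on 22 electrodes has smallest
eigenvalue ≈ 6e-8, so any larger ridge visibly breaks interpolation at the
electrode sites (site error ~1e-3 is reached at 1e-10; larger ridges give
errors of order one).

Maps are rendered on a fixed 42 × 56 grid (rows × columns, nose up, left
ear at −x) with the head disk inscribed and centred; pixels outside the
disk are exactly 0, so the CNN always sees a rectangular input.  The disk
rim is drawn at 72° polar angle (`EXTENT = 0.8`) rather than at the
equator: the cap only reaches 54° from the vertex, and an equator-rim view
crowds all electrodes into the central 60 % of the image where the conv +
pool blur (≈3 px) exceeds the inter-electrode spacing, while devoting the
outer 40 % of the radius to spline extrapolation that carries no electrode
information.  Electrode pixel positions and the inverse projection share
the same scale, so geometry checks (peak-at-electrode, mirror symmetry)
are unaffected by this choice.

Image intensity scaling is configurable.  Per-image min–max scaling to
[0, 1] is available, but the default for experiments is a single per-band
scale (division by the dataset-wide maximum absolute value): a per-image
normaliser is a function of the image extremes, which sit at the most
active source, so it couples every pixel to the class signal and smears
the spatial localization that the relevance analysis is meant to recover.

## The CNN

Per input branch: convolution with I = 2 kernels of 3 × 3 (stride 1, zero
padding, ReLU), then 2 × 2 max-pooling with stride 2 (42 × 56 → 21 × 28).
The pooled maps are concatenated, flattened, batch-normalised, passed
through a dense layer of h_u ReLU units with Elastic-Net regularization,
batch-normalised again, and classified by a softmax layer with one unit
per class.  Training minimises the MSE between the softmax output and the
one-hot labels with Adam at learning rate 1e-3 (read from the notation
"exp(−3)"; e⁻³ ≈ 0.05 would be implausibly high for Adam and the learning
rate is exposed in the config either way).  Cross-entropy is available
behind a flag.  The pool stride is 2 even though the source description
says "stride of one sample": the printed 42 × 56 → 21 × 28 reduction and
the flatten arithmetic are only consistent with stride 2 and are treated
as authoritative.

Two readings of the multi-band layer sizing coexist in the source
material and both are supported via `band_mode`:

* `branches` (default): one convolution per band, flatten length
  G·G′·I·N_f (4704 for scenario D) — the dimension the relevance
  construction states, and the only reading that yields per-band relevance
  maps;
* `channels`: the band maps are input channels of a single convolution
  producing two feature maps in total, flatten length 21·28·2 = 1176 — the
  sizing printed in the layer table.

The implementation is plain NumPy (im2col convolution, hand-derived
backward passes, Adam); with ≤2 kernels and 42 × 56 inputs this trains in
seconds per fold on one CPU and is bit-reproducible given the seed.
Batch-norm uses momentum 0.99.  Early stopping on a 10 % validation split
(patience in epochs) is available and disabled (`patience=0`) in the
pipeline defaults, which instead run a fixed 80 epochs at batch 64.

**Batch-norm ε as a variance floor.**  ε defaults to 1e-3 (the usual
framework value) but the pipeline raises it to 0.2.  With a tiny ε the
standardisation multiplies near-constant pixels — the spline values just
outside the electrode ring — by 30× or more; these pixels are weakly but
systematically class-correlated (the spline has global support), so the
network learns to read the class from amplified background, and the
back-projected relevance develops a bright ring at the head-disk rim with
no electrode underneath.  This is the "false augmentation of background
localities" phenomenon familiar from weight-based interpretation of
backward models.  A variance floor of 0.2 (image intensities are in
[−1, 1] after global scaling) caps that amplification at ≈2×, leaves
classification accuracy unchanged in our experiments, and makes the
relevance maps track the discriminative sources.  Classification results
are insensitive to ε; only interpretability is at stake, and ε remains a
config field.

Mild ridge shrinkage (l2 = 0.003, l1 = 0) is the pipeline default: the
ridge's grouping behaviour distributes weight across correlated
informative features (both lateralised sources in a binary task) instead
of selecting one, and drives the weights of uninformative features toward
zero, which is what makes the weight-norm relevance meaningful.  The
hyperparameter grid search (h_u ∈ {50,…,550}, l1, l2 ∈ {0.001, 0.01, 0.1})
is implemented and scores every combination by stratified CV.

**Input dropout.**  The pipeline trains with spatial input dropout
(probability 0.5 of zeroing each input pixel, with the usual 1/(1−p)
rescaling).  Without it, shrinkage prunes *redundant* discriminative
sites: in a binary left-vs-right task either hemisphere alone supports a
perfect rule, so some fits carry no weight at all on the second source
and no post-hoc attribution can recover it.  Randomly occluding input
pixels makes single-site strategies fragile and forces every fit to keep
evidence from both hemispheres.  Classification accuracy at the synthetic
study conditions changes by at most a few points; the benefit is entirely
in the stability of the relevance maps.  Dropout probability is a config
field (`input_dropout`, 0 disables).

The model can enforce the head-disk mask on its input (`input_mask`),
zeroing off-disk pixels in the forward pass; the pipeline always feeds
masked images, so this is numerically a no-op on pipeline data but makes
off-scalp input perturbations provably unable to move predictions.

## Relevance back-projection

For the first dense layer after the flatten, W ∈ R^{D×h_u}, the relevance
of feature d is the row norm ϱ_d = ‖w_d‖_p with p = 2 (the "generalized
mean" order is left open in the source; 2 is the natural Euclidean
choice).  ϱ is unflattened into per-(band, kernel) 21 × 28 maps — the
exact inverse of the model's flatten — averaged over kernels, bilinearly
upsampled to 42 × 56 (the "extrapolation operator" is unspecified;
bilinear is the minimal smooth choice), and masked to the head disk.

Relevance is aggregated as the mean map over the cross-validation fold
models of the best window rather than from a single fit: with two
redundant discriminative sites (either hemisphere alone suffices for a
binary rule), an individual fit often leans on only one of them, while
the fold ensemble exposes both.

**Electrode attribution.**  Two scorers are provided.  The
`neighbourhood` scorer averages the map in a 2-px disk around each
electrode's projected pixel — simple, but it cannot distinguish a source
from its spline shoulder: the rendered bump around electrode e *is* the
spline kernel centred at e, so the immediate neighbours necessarily sit
at a substantial fraction of the peak.  The default `unmix` scorer
therefore deconvolves that point-spread at the score level: it measures,
with the same neighbourhood-mean operator, the response of every
electrode's score to a unit bump rendered at every other electrode, and
solves a small nonnegative least-squares problem (22 unknowns plus a
constant background) for the electrode weights that best reproduce the
observed scores.  Each bump is thereby attributed to the electrode that
generated it.  The neighbourhood scorer remains available for
comparison.

## Spatial dropping

* `sensorimotor_prior`: restrict data and montage to the 10 motor-cortex
  electrodes (C3, C1, Cz, C2, C4, CP3, CP1, CPz, CP2, CP4) before any
  training; the spline is refit on the reduced montage and the image grid
  is unchanged.
* `relevance_threshold`: after a full fit, keep electrodes whose
  max-over-bands score reaches the specified quantile (default 0.75) of
  all scores, with ties kept and a floor of 4 electrodes filled by rank;
  then re-run the entire pipeline (features → maps → CV) on the retained
  subset.  Thresholding operates once per dataset on the fold-aggregated
  relevance, not per fold.  The quantile threshold itself is our choice;
  no numeric threshold is stated in the source material.

## Evaluation

Accuracy is trace/total of the confusion matrix; Cohen's κ =
(a_c − p_e)/(1 − p_e) with p_e = 1/2 (two classes) or 1/3 (three).
Cross-validation is stratified 10-fold, repeated 10 times with reshuffled
partitions by default (`sklearn` RepeatedStratifiedKFold); fold partitions,
model initialisation and batch order all derive from the run seed.  The
comparison between dropping strategies uses Welch's unequal-variance
two-sample t-test on fold scores ("paired Welch" is contradictory — Welch's
test is unpaired — so the unpaired test is the default and a paired t-test
sits behind a flag), with the degenerate zero-variance case defined as
p = 1 for equal means and 0 otherwise.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:
per-trial 1/f background noise (power exponent 1) at all 22 electrodes,
plus 10 Hz (μ) and 22 Hz (β) oscillators sourced at C3, C4 and Cz with
random phase per trial and source.  During 3–6 s the source mapped to the
trial's class (right hand → C3, left hand → C4, foot → Cz — the
contralateral mapping, with ERD as a power *decrease* matching sensorimotor
physiology) is attenuated by `erd_depth` in amplitude.  Sources spread to
neighbouring electrodes with Gaussian weight exp(−d²/2σ²) in unit-sphere
chord distance, σ = 0.15; at that width the first-neighbour amplitude
weight is 0.12 (<2 % in power), so the class-dependent power drop stays
localised at the named source — the premise of the planted-truth recovery
tests — while the same kernel, variance-normalised, mixes the noise so
channels are realistically correlated.  Oscillator amplitudes are
calibrated against the realised background so that `snr` is the ratio of
rhythm band power to background band power at the source electrode; the
calibration compares Welch band sums of the generated noise and of a
unit-amplitude reference tone, making it invariant to PSD scaling
conventions.

What the generator does **not** emulate: volume conduction through a
realistic head model, artifacts (blinks, muscle), non-stationary background
statistics, inter-subject variability, and μ/β phase coupling.  Passing the
recovery suites therefore shows the pipeline is correct and sensitive under
its own assumptions, not that it attains any particular accuracy on real
recordings.

## Desk-scale protocol sizes

The property and recovery suites are sized for a single CPU: recovery runs
use scenario A (μ band) on the analysis window starting at 3 s (the MI
interval), 100 trials per class, stratified 10-fold CV with one repeat,
h_u = 50, 80 epochs at batch 64.  These are the package's standard
desk-scale settings; the full protocol (all five windows, 10 × 10 CV,
grid-searched h_u) is available through the same configuration objects.

## Known limitations

* Weight back-projection inherits the usual caveats of interpreting
  backward-model weights; the variance floor and the unmixing scorer
  mitigate, but do not remove, its biases.  Gradient or perturbation
  saliency is deliberately out of scope.
* The printed-layer-table (`channels`) and equation-level (`branches`)
  readings of the architecture disagree in the source material; both are
  implemented, and the branch reading is the default because per-band
  relevance requires it.
* Per-subject accuracies on the external competition recordings are not
  reproduced here; the synthetic recovery suites stand in for them at desk
  scale.
* The three-class κ uses p_e = 1/3; published three-class κ values are not
  all consistent with their printed accuracies under any fixed p_e, so only
  internally consistent pairs are used as checks.
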