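# Methods

`portaldose` converts flood-field-corrected grayscale portal images (mPI)
acquired by an amorphous-silicon EPID into planar absolute dose
distributions (mPD) at the isocenter plane, and scores them against
predicted portal dose (pPD) with global 2D gamma analysis. This note
documents the model, the synthetic data it is developed against, the
numerical choices, and what the tests do and do not demonstrate.

## The conversion problem

A flat-panel EPID images the treatment beam with no patient in between
(non-transit geometry). Its signal is linear with dose but spectrally and
spatially biased relative to dose-to-water, and clinical images are stored
after flood-field correction — division by an open-field reference frame.
That correction flattens the panel response, but it also divides out the
beam's own off-axis modulation (the "horn" produced by the flattening
filter). The horn is therefore present in the reference dose while being,
by construction, *absent from the input image*. Any image-to-dose model
must re-inject it from pixel position alone.

## Model

The network is a U-net operating on a single-channel image and returning a
single-channel map of the same size:

* encoder: 4 levels, each two 3x3 zero-padded ("same") convolutions + ReLU,
  kernel counts 8, 16, 32, 64, followed by 2x2 max pooling;
* bottleneck: two convolutions at 128 kernels;
* decoder: 2x nearest-neighbor upsampling, concatenation with the
  equal-resolution encoder output (skip connection), then two convolutions
  at 64, 32, 16, 8 kernels;
* final block: the two 8-kernel convolutions of the last decoder level plus
  a linear 1x1 single-kernel convolution that collapses the channels to one
  dose plane (three convolutions in total);
* no dropout, no batch normalization, no loss regularization.

Weights are Glorot-uniform, biases zero. With the defaults the network has
490 993 trainable parameters, which the test suite checks against the
closed-form sum of (k^2 c_in + 1) c_out over all convolutions.

**True Dose Modulation (TDM).** The positional information erased by the
flood field is restored by a non-trainable positive map multiplied onto the
network output (Hadamard product). It is computed from a single calibration
beam — a 260 mm open square that covers the whole panel — as the ratio of
that beam's reference dose to the stage-1 network's own inference of it.
Where the stage-1 inference falls below `eps_fraction` (default 0.01) of
its maximum, the ratio is replaced by 1.0; because the calibration field
covers the panel, this guard only touches numerically tiny border pixels.

**Two-step training.** Stage 1 trains the bare U-net (Adam, MSE,
learning rate 1e-3). The TDM is then computed and attached, and stage 2
fine-tunes all U-net parameters at 1e-4 with the TDM frozen. A transient
loss increase at attachment is expected and recorded in the history; the
fine-tune recovers it. Callbacks in both stages: reduce-on-plateau learning
rate (factor 0.8 after 4 epochs without strict validation improvement),
early stopping (5 stagnant epochs), and best-validation-state restoration.
Adam uses beta1 = 0.9, beta2 = 0.999, epsilon = 1e-6; batches hold 4
samples (2 in the tiny test fixtures) and are reshuffled every epoch from
the run seed. The plateau scheduler is re-initialized at attachment.

The neural-network layer stack (convolutions expressed as per-tap BLAS
matmuls, pooling, upsampling, backprop, Adam) is implemented in numpy
inside the package (`portaldose.nn`); arrays are NHWC float32, and all
computations are deterministic for a fixed seed on one device.

**Cross-validation and model selection.** `split_folds` partitions the
dataset into k near-equal disjoint test sets (sizes differ by at most one;
at the full scale of 186 samples and k = 5 this gives test sizes
37/37/37/37/38 and a 119/30 train/validation split of the remaining pool).
`select_model` picks the fold with the lowest mean test gamma, breaking
ties toward the higher passing rate, then the lower fold id.

## Preprocessing

* **Edge correction.** A border of `crop_px` pixels is discarded and
  refilled with the nearest interior pixel value (corners take the interior
  corner). The width scales with resolution, `crop_px = round(32 n / 1024)`
  (32 px at 1024, i.e. a 7.7 mm physical border; 4 px at the 128 desk
  scale). It is applied to images, doses, *and* the TDM calibration pair,
  which is why TDM profiles go linear over their first and last
  millimeters. The operation is idempotent and leaves the interior
  untouched.
* **Normalization.** Inputs are divided by the central pixel value of the
  80 mm square beam's portal image (grayscale units), targets by the
  central pixel of its reference dose (Gy). The dose-side factor doubles as
  the absolute calibration of inferred maps, so
  `calibrate(normalize(x, f), f) = x` exactly.
* **Central pixel.** On an even n-sided grid the "central pixel" is
  (n/2, n/2) 0-based, and the beam axis passes through that pixel's center.
  A consequence worth noting: mirror symmetry of centered beams holds about
  the central *pixel* (index c + k maps to c - k), not under a raw array
  flip, which on an even grid shifts everything by one pixel.

## Gamma analysis

Global gamma index per reference pixel r above the low-dose threshold
(default 10 % of the maximum reference dose):

    gamma(r) = min_d sqrt( (|d|/dta)^2 + ((D_eval(r+d) - D_ref(r)) / (tol/100 * max D_ref))^2 )

with defaults tol = 2 %, dta = 2 mm. The displacement search walks a
sub-pixel lattice (spacing pitch/subsample, default subsample 10; the
evaluation harness uses 5) out to 3 x dta, with the evaluated map bilinearly
interpolated; displacements that leave the grid are skipped. The lattice is
sorted by |d| so the vectorized engine can stop as soon as the pure
distance term exceeds every pixel's current minimum. A pixel passes when
gamma <= 1 (inclusive). `brute_force_gamma` runs the same definition as an
explicit per-pixel loop with its own inline interpolation and is the
reference oracle on grids up to 64^2; at matched lattice settings the two
agree to floating-point precision.

Dose-error statistics over the same analysis region: the absolute error is
the mean |D_eval - D_ref| in Gy ("local"), the relative error is that mean
divided by the maximum reference dose, in percent ("global"). The reference
side of all comparisons is the predicted dose (pPD); thresholds and the
dose-difference normalization use its maximum.

## Synthetic beam simulator

Clinical portal-dosimetry datasets are not redistributable, so the package
ships a physics-inspired simulator whose statistical structure matches what
the model must learn. For a step-and-shoot beam described by per-segment
leaf apertures and monitor units (MU):

* **Fluence** is the MU-weighted sum of binary apertures, rasterized by a
  pixel-center rule (a pixel is open when its center lies inside the
  aperture); penumbra comes from the blur kernels, as in portal physics.
  Leaf pairs are stacked bands spanning the field of view; square
  calibration beams are rasterized directly. A clinical segment extending
  beyond the panel is a geometry error; an oversized calibration square
  (the 260 mm TDM beam on the 245.76 mm panel) is clipped with a
  "protruding" warning, which is also what exercises the edge correction.
* **Dose** (pPD): Gaussian blur (sigma 2.5 mm) of fluence x OAR, where
  OAR(r) = 1 + 0.03 (r/100 mm)^2 + 0.01 (r/100 mm)^4 is the radially
  symmetric horn, about +4 % at 100 mm off axis — the magnitude typical of
  flattened 6 MV beams. Dose is normalized so the central pixel of the
  80 mm / 100 MU square equals dose_per_mu x 100 MU = 0.8 Gy.
* **Portal image** (mPI): the same fluence x OAR, additionally weighted by
  a radial panel response (-1.5 % at 100 mm), blurred by a *different*
  kernel — a sharp 1.2 mm Gaussian plus 8 % long-range glare at 20 mm —
  then divided by the open-field flood map (normalized to 1 on the beam
  axis), scaled so the reference square's center sits near mid-range
  (30 000 G.U.), degraded with Gaussian read noise (sd 30 G.U.; integrated
  high-count images justify Gaussian over Poisson) and quantized to 16
  bits. Flood-field division removes the horn and panel response from the
  image by construction.
* **Clinical-like beams**: 3-10 segments per beam, a contiguous random band
  of open leaf pairs (field heights 50-170 mm), random aperture center and
  width, per-leaf jitter smoothed across adjacent leaves (spatial
  correlation), and random per-segment MU in 4-16.

Presets: the desk scale uses a 128-pixel grid at 1.92 mm pitch and 32 leaf
pairs; the paper scale 1024 pixels at 0.24 mm and 80 pairs. Both preserve
the 24.5 cm field of view. Dataset generation is bitwise deterministic for
a fixed (config, seed): one seed sequence fans out to named per-beam
sub-seeds, so stages can be re-run independently.

What the simulator deliberately does *not* model: Monte-Carlo or
collapsed-cone transport, MLC transmission and tongue-and-groove, beam
spectra, panel ghosting/lag, and setup variability between acquisitions.
Passing the synthetic studies therefore demonstrates that the architecture
and two-step procedure can recover an erased off-axis modulation and invert
detector blur at clinically relevant tolerances — not that any particular
clinic's beam model is reproduced.

## Study problem sizes and expected numbers

The end-to-end studies run at desk scale: 40 training / 10 validation
clinical beams, 10 held-out clinical controls, the 6 evaluation squares,
and epoch caps of 30 (stage 1) and 15 (fine-tune) — early stopping usually
fires near those caps. One such run takes a couple of minutes on a single
CPU core. Typical seed-averaged results, recomputed by
`scripts/acceptance.py`: TDM-vs-true-horn RMS around 1 % of the profile
over the central 80 % of the calibration field; gamma passing rate
(2 %-2 mm > 10 % Dmax) around 99 % with the TDM and around 98.5 % without
it on held-out clinical beams; around 95 % vs 90 % on the square controls,
which are out-of-distribution for a model trained on clinical shapes only —
squares are harder, and the TDM's contribution shows most clearly there.

## Numerical notes and limitations

* Quantization and glare-kernel truncation at the panel border make portal
  images of centered beams mirror-symmetric only to +/-1 G.U.; dose planes
  are symmetric to 1e-12 relative.
* ReLU pre-activations that are exactly zero (zero-initialized biases)
  make finite-difference gradient checks disagree with any single
  subgradient choice; the test suite checks gradients with biases nudged
  off the kink, in float64.
* The gamma engine's early exit is lossless: the lattice is sorted by
  displacement length, and the search stops only when no pixel can improve.
* `brute_force_gamma` refuses grids above 64^2; it exists for correctness,
  not speed.
* Learning-rate traces are non-increasing within a stage and reset at TDM
  attachment; histories record the attachment epoch, per-epoch losses and
  learning rate, and optionally gamma statistics on a monitor set every
  5 epochs (off by default in the studies to save time).
* The data-amount study defaults to a handful of sizes at desk scale; the
  statistical-significance tests sometimes reported alongside such tables
  are out of scope — seeded bootstrap confidence intervals of paired
  per-beam differences are provided instead.
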