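# Methods

## Problem and model

Ring and semi-ring artifacts in X-ray tomography originate from the
nonlinearity and inconsistency of individual detector pixels: a defective
pixel writes a (possibly partial) constant **stripe** down one column of the
sinogram, which filtered back projection (FBP) smears into a concentric ring
in the reconstructed slice.  Removing the stripes before reconstruction
removes the rings.

This package removes stripes with a residual convolutional network that
operates in the Haar wavelet domain.  A sinogram is decomposed by one level
of the 2-D Haar discrete wavelet transform into four half-resolution
sub-bands (approximation WA, horizontal WH, vertical WV, diagonal WD).  The
network maps the four corrupted sub-bands to the four *stripe components*
(S_WA, S_WH, S_WV, S_WD) — the artifact, not the clean image.  Subtracting
the prediction from each band and inverting the transform yields the
destriped sinogram.  Working at half resolution quarters the pixel count,
and predicting the artifact (a residual-learning target) is an easier
regression problem than predicting the clean content.

### Network

14 convolution layers: a 3×3 conv 4→64 with ReLU, six residual blocks
(conv 64→64 → ReLU → conv 64→64, identity shortcut, ReLU — the classic
post-activation residual unit), and a linear 3×3 conv 64→4.  Stride is 1
everywhere and padding preserves spatial size: down-sampling would destroy
the one- to few-pixel-wide stripes the network must localize.  With biases,
the parameter count is (9·4·64+64) + 6·2·(9·64·64+64) + (9·64·4+4) =
447 812.

Choices the architecture description leaves open, resolved here:

* **Conv padding:** replicate (edge), 1 px.  Zero padding would fabricate
  an intensity step at the detector edges and bias border stripes.
* **Final layer:** linear (no ReLU) — artifact coefficients are signed.
* **Normalization layers:** none; the layer inventory is convolutions and
  ReLU only.
* **Weight init:** He fan-in normal, seeded; biases zero.
* **Input scaling:** by default each sample's coefficient stack is divided
  by its standard deviation before the network and the predicted artifact
  is multiplied back (`CorrectionModelSpec.input_scale="std"`).  Sinogram
  intensities scale with object mass and exposure; a scale-free network
  generalizes across that and keeps He-initialized activations in a sane
  range.  Set `input_scale="none"` to feed raw coefficients.

### Loss

`L = L_M + λ·L_W` with

* `L_M = MSE_WA + MSE_WH + MSE_WV + MSE_WD`, each term the mean squared
  error between the predicted and true artifact in one sub-band
  (`MSE = (1/N)·Σ(P_i − P̂_i)²`, N = pixels in the band);
* `L_W = ‖∇S_WA‖ + ‖∇S_WH‖`, the smoothness of the predicted stripe
  components along the stripe direction (stripes vary little along their
  own axis).  `∇` is the forward finite difference along the angle axis and
  `‖·‖` defaults to the mean of squared differences (an L1 option exists).

Open points resolved here: `L_W` penalizes the *prediction* (the stripe
component), not the residual.  The WA/WH band selection is kept as the
canonical definition but is overridable (`LossConfig.smooth_bands`) because
which bands carry stripe energy depends on the orientation convention —
under this package's row=angle convention a detector stripe lands in WA and
WV.  λ defaults to 0.1, chosen so the two terms are of the same order under
the default stripe model; `losses.calibrate_lambda` re-balances the terms
on a pilot batch when the stripe statistics differ.

### Haar normalization

Orthonormal scaling (each 2×2 block contributes with weight 1/2), so the
transform preserves energy and wavelet-domain MSE is commensurate with
image-domain MSE.  Odd-sized sinograms are replicate-padded by at most one
row/column before the transform and cropped exactly after the inverse.
Blocks anchor at index (0,0); a single decomposition level is used.

## Synthetic data

Paired data are manufactured because labeled beamline data are scarce:

1. **Phantoms** — random overlapping ellipses/rectangles with smooth linear
   intensity ramps on a circular support, values in [0,1], fully seeded.
   They stand in for a natural-image corpus so nothing is downloaded; a
   folder loader (grayscale + center crop) accepts user images.
2. **Radon transform** — parallel-beam, inscribed-circle support
   (scikit-image); the reference protocol is 360 projections over 0–179.5°.
3. **Stripe injection** — the artifact statistics are deliberately simple
   and explicit (`StripeSpec`): the stripe count is uniform in [5, 30],
   widths uniform in {1,2,3} px, additive amplitudes uniform in ±[0.02,
   0.15] of the clean sinogram's dynamic range, and 30% of stripes span
   only a random contiguous angular interval (semi-rings).  A
   multiplicative (constant-gain) mode exists but is off by default.

The training label is `hdwt(corrupted) − hdwt(clean)`, which by linearity
equals the transform of the artifact field.

What the generator does **not** emulate: photon/readout noise, beam
hardening, intensity drift, detector cross-talk correlations, fan/cone
geometry, and the texture richness of natural images.  Passing tests show
the method removes the stripe family it was trained on from piecewise-
smooth objects; they do not certify performance on real beamline data —
that is exactly what the transfer-learning path is for.

## Training

Adam (lr 1e-3, β = 0.9/0.999), batch 8, best-validation-loss checkpoint
returned.  Fine-tuning uses lr 1e-4 by convention.  `coefficient_mode`
implements the ablation: `complete` feeds all four sub-bands; `related`
zeroes the WV/WD input channels (one 4-channel architecture in both modes,
so checkpoints stay interchangeable — an interpretation, flagged here).
Training is bit-deterministic for a fixed seed (`deterministic_mode`,
single-threaded numpy).  A non-finite loss aborts with the last finite
parameters attached.  Full coefficient planes are trained on at package
scale; `patch_size` enables random-crop patching for large detectors.

## Fourier–wavelet baseline

The classical comparison method: multi-level DWT (default `db4`, 4 levels);
in each level's vertical-detail band (where column stripes condense) the
1-D FFT along the angle axis is damped by `1 − exp(−k²/(2σ²))` (default
σ = 2 frequency bins); reconstruct.  Only detail bands are damped: damping
the final approximation would also delete legitimate angle-constant
content, e.g. the sinogram of a centered disc.

## Evaluation

PSNR uses the reference image's dynamic range by default (a fixed-range
override exists for cross-sample comparability); identical images report an
infinite sentinel.  SSIM is the standard Gaussian-window formulation,
clipped to [0,1].  Slice metrics are computed inside the reconstruction
support circle only.  The evaluation harness always includes the identity
("no correction") method as the floor and aggregates per degradation bin,
where degradation is the corrupted-vs-clean sinogram PSNR.

## Scaled study conditions

The packaged studies run on one CPU in minutes; sizes are package choices:

* **End-to-end efficacy** (`experiments.run_end_to_end`): 200 sinograms
  (64×64 phantoms, 90 angles), default stripes, 80/20 split; network at
  32 hidden channels / 3 residual blocks (8 conv layers), 40 epochs.
  Reported: mean test-set PSNR/SSIM uncorrected vs corrected (and the FW
  baseline).
* **Ablation** (`run_ablation`): complete vs related mode under identical
  budgets and seeds — 120 samples (48-px phantoms, 64 angles), 16 channels
  / 2 blocks, 30 epochs, 3 seeds; compared by median held-out wavelet loss.
* **Transfer** (`run_transfer`): per seed, pretrain on the default stripe
  distribution, then adapt to a shifted distribution (widths 4–8 px,
  amplitudes ±[0.05, 0.25]) with 20 training samples for 12 epochs, either
  fine-tuning (lr 1e-4) or from random init (lr 1e-3); compared by median
  best validation loss.

The reduced-width training network is the same architecture family as the
full 14-layer model (which is what `build_model()` constructs by default);
width and depth are scaled down purely so a training run fits interactive
time scales.

## Known limitations

* The stripe model is stylized; real flat-field residuals drift in time and
  couple to intensity, which only the fine-tuning path addresses.
* The Radon/FBP pair is scikit-image's discretization; mass conservation
  holds to ~1% and round-trip NRMSE to <0.1, which bounds but does not
  eliminate discretization error in slice-level metrics.
* The network is trained per stripe distribution; strong distribution shift
  without fine-tuning degrades gracefully but measurably.
* Training runs on the CPU in float32; there is no GPU path.
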