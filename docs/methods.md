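# Methods

`motioncorr` implements a complete desk-scale testbed for studying how MRI
motion artifacts distort voxel-based-morphometry (VBM) atrophy scores and
how well a conditional GAN can undo that distortion.  It has five
computational parts: a synthetic phantom generator, a k-space artifact
simulator, a Pix2Pix correction network with a U-Net baseline, a normative
Z-score atrophy scorer, and agreement statistics.  This note records the
models, the conventions chosen where several were defensible, and what the
phantom experiments do and do not establish.

## Motion-artifact model

A motion condition is a pair (RA, KI): a rotation angle in degrees and a
k-space zero-fill interval in pixels.  For one slice `I` the simulator
computes

1. `I_L = rot(I, +RA)`, `I_R = rot(I, -RA)` — rotation about the image
   center, bilinear interpolation, zero fill outside the frame;
2. `K_L = F(I_L)`, `K_R = F(I_R)` — centered, orthonormal 2-D FFTs (Parseval
   holds with no rescaling);
3. zero-filling: every KI-th phase-encode row of each spectrum is set to
   zero.  Row indices are taken in DC-at-origin coordinates and the DC row
   itself is exempt, so global contrast survives; for a 256-row spectrum and
   KI = 10 exactly 25 rows are zeroed.  KI = none leaves the spectrum
   untouched.  Both the index offset and the DC exemption are arguments of
   `zero_fill_lines` for sensitivity analyses;
4. merging: the top half of `K_L` (the left rotation, by convention —
   `merge_halves` takes its arguments in that order) is joined to the bottom
   half of `K_R`;
5. reconstruction: the merged spectrum is no longer Hermitian-symmetric, so
   its inverse transform is complex; the pipeline returns its magnitude, as
   in standard MR magnitude reconstruction.

The identity condition (RA = 0, KI = none) bypasses the pipeline entirely
and returns the input array unchanged, so "no motion" is exact rather than
a rotate/transform round trip.  Larger RA and smaller KI produce stronger
ghosting; on a fixed phantom slice SSIM decreases monotonically along both
axes of the 4 x 4 trained grid (angles {0, 1, 2, 3} degrees x intervals
{none, 10, 20, 30} px).  Two further conditions, 1.5deg_25 and 2.5deg_15,
are reserved for testing generalization to unseen motion.

Training datasets pair each retained slice (every third, starting at slice
0) with its 16 artifact versions.  For a cohort of 51 volumes x 176 slices
this nominal count is 51 x 176 x 16 / 3 = 47,872 pairs;
`nominal_pair_count` exposes the formula.

## Phantom generator

Each phantom slice is a superposition of smooth analytic shapes on a
256 x 256 (or smaller, power-of-two) grid with intensities in [0, 1]: an
elliptical head of soft tissue (0.35), a gray-matter band (an elliptical
annulus at ~0.9 total), a dark ventricle, and two bright Gaussian blobs
standing in for the hippocampi.  The blob disks define the VOI mask; the GM
band plus the VOI defines the GM mask, so the VOI is a subset of GM by
construction.  Structures shrink smoothly toward the ends of the slice
stack.

Between-subject variability comes from a seeded per-volume jitter of
ellipse size (+-4 %), GM brightness (+-6 %) and VOI brightness (+-6 %), plus
a per-slice spatially smooth intensity field (Gaussian-filtered white
noise, sigma 1.5 px, SD 0.02, confined to the head) emulating anatomical
texture, and uncorrelated acquisition noise of SD 0.002.  The smooth field
is the dominant noise term deliberately: pixel-wise white noise at
realistic amplitudes puts a hard ceiling on the SSIM any smooth
reconstruction can reach, which is a property of white noise rather than of
motion correction.

Atrophy is one scalar in [0, 1]: level `a` multiplies the VOI blob
amplitude by (1 - 0.70 a) and its radius by (1 - 0.35 a), so mean VOI
intensity decreases strictly and recoverably with `a`.  `inject_atrophy`
regenerates the volume from its stored seed at a new level, leaving all
tissue outside the blobs bit-identical.  Everything is deterministic given
(seed, parameters).

What the phantom does *not* emulate: real anatomy, tissue segmentation
boundaries, multi-contrast physics, through-plane motion, or clinical
artifact severity.  Phantoms are much smoother than brain MRI, so absolute
artifact SSIMs (~0.67-0.91 across the test grid) sit far above the
0.22-0.37 range seen on clinical data; all conclusions drawn from phantoms
are therefore about orderings and directions, not absolute values.

## Correction networks

The generator is a U-Net: encoder of stride-2 4 x 4 convolutions (LeakyReLU
0.2 applied to the input of the second and subsequent layers, batch
normalization on outputs from the second layer on, none on the innermost
level), a mirror decoder of stride-2 4 x 4 transposed convolutions (ReLU
inputs, batch-normalized outputs) with skip connections concatenating each
encoder level to its decoder mirror, and a tanh output in [-1, 1].  Depth
is log2 of the image side, capped at eight levels (eight at 256 x 256, six
at the 64 x 64 test size); channels run base x {1, 2, 4, 8, 8, ...} capped
at 8 x base (base 64 at full scale).  Kernel size, stride and the channel
schedule follow common Pix2Pix practice; weights start from N(0, 0.02).

The discriminator is a PatchGAN over (reference, candidate) image pairs:
each image is cropped into 32 x 32 patches (64 patch pairs for a 256 x 256
matrix, 4 at 64 x 64), each patch of the pair is convolved once in its own
branch, the branch features are concatenated and convolved again
(batch-normalized, LeakyReLU), flattened through a dense layer into a
two-class softmax per patch, and all patch outputs are then concatenated
into a second, global two-class softmax.  A true pair presents the
reference image twice; a false pair presents the reference and a generated
image.  The two-class softmax is retained as such rather than collapsed to
a sigmoid.

Training alternates one discriminator update and one generator update per
mini-batch with Adam (beta1 0.9, beta2 0.999, constant learning rate).  The
discriminator minimizes binary cross-entropy on both heads over true and
false pairs; the generator minimizes the adversarial cross-entropy plus
lambda x L1 to the clean target with lambda = 100, so the L1 term dominates
and the adversarial term sharpens high-frequency content.  The U-Net
baseline is the identical generator architecture trained alone with mean
squared error.  Images are mapped to [-1, 1] by the training cohort's
min-max before training; the inverse map is stored with the model and
applied (with clipping at zero) at inference.  Validation is split by
volume, never by slice; all randomness (initialization, shuffling, splits)
descends from one seed, and two runs with the same seed produce identical
losses.  Non-finite losses abort with a diagnostic.  Every layer's backward
pass is verified against central finite differences in the test suite; the
layer stack is implemented directly on numpy arrays.

The full-scale configuration (100 epochs, batch 32 for Pix2Pix and 16 for
the U-Net, learning rate 1e-4, base 64 channels) is the package default in
`TrainingSpec`.  The desk-scale experiments that the tests run use a
reduced configuration chosen to fit one CPU: 8 training volumes x 2
retained 64 x 64 slices x 16 conditions = 256 pairs, 20 epochs, batch 16,
base 24 channels, learning rate 3e-3 (the higher rate compensates for the
short schedule; at 1e-4 a 20-epoch run barely leaves initialization).
Under that configuration the Pix2Pix correction raises held-out SSIM above
the artifact level for every motion-bearing condition, including the two
untrained ones, and outperforms the U-Net baseline on all conditions.

## Atrophy scoring

A normative model holds the per-voxel mean and sample SD (ddof = 1) of a
normal-control phantom cohort; the SD is floored at 1e-6 of the cohort
intensity range to keep Z finite at zero-variance voxels.  A patient
volume's Z-map is `Z = (mean_NC - patient) / SD_NC`, so positive Z means
darker than normal, i.e. apparent tissue loss.  Three indices summarize it:

- severity of VOI atrophy — the arithmetic mean of Z over the VOI mask.  A
  `positive_only` variant averaging max(Z, 0) is available, since the
  clinical convention is not fully specified; the plain mean is the
  default.
- extent of GM atrophy — 100 x |{GM voxels with Z > 2}| / |GM|, strict
  inequality (Z exactly 2 does not count).
- extent of VOI atrophy — the same fraction over the VOI mask.

Phantom cohorts are generated co-registered, so the spatial normalization,
segmentation and DARTEL registration of a clinical VBM pipeline are
replaced by the identity.  That substitution has a visible consequence:
on phantoms, artifacts reliably inflate the *extent of GM atrophy* (ghosting
smears the bright GM band, darkening it in place), but the *severity of VOI
atrophy* does not inflate — the VOI sits near the rotation center where
displacement is a fraction of a blob radius, and at a 64-px matrix the
fixed zero-fill intervals remove near-DC rows whose rectified ringing
slightly brightens the VOI.  In the clinical pipeline the inflation of VOI
scores is mediated by segmentation assigning less gray matter to blurred
tissue, a step deliberately out of scope here.  The agreement analyses
therefore compare absolute biases rather than assuming a sign.

## Statistics

- SSIM: scikit-image's implementation with the canonical constants
  K1 = 0.01, K2 = 0.03, Gaussian weighting (sigma 1.5, 11 x 11 window) and
  population local covariances; dynamic range defaults to the joint
  max - min of the pair.  The test suite checks it against an independent
  sliding-window implementation to 1e-6.
- Bland-Altman: for series x (candidate) and y (reference), differences
  d = x - y give the mean bias and limits of agreement bias +- 1.96 x
  sample SD.
- Spearman rank correlation: scipy's implementation (mean ranks for ties,
  large-sample p-value); constant input raises rather than returning an
  undefined coefficient.  No multiple-testing correction is applied.
- Weighted Cohen's kappa for 5-point Likert ratings: linear weights by
  default, quadratic by flag; computed from the observed and expected
  contingency tables as 1 - sum(w O) / sum(w E).

`evaluate_suite` assembles the report: per-condition SSIM mean +- SD for
artifact, U-Net and Pix2Pix images against the originals, and per-condition
Bland-Altman bias/limits plus Spearman rho for each atrophy index, with the
original-image scores as reference.  Atrophy scoring inside the suite works
on the retained-slice stacks, so the normative model must be fitted on
control stacks with the same slice retention.

## Numerical and design choices

- Orthonormal FFT normalization so spectral energy equals image energy.
- Rotation uses bilinear interpolation without spline prefiltering; the
  zero-angle path returns the input exactly.
- The zero-fill row convention (DC-at-origin indexing, DC exempt) is one of
  several readings of "filling k-space with zeros at equal intervals"; it
  was fixed because it preserves global contrast, and both switches are
  exposed.
- Batch normalization starts at the second encoder layer (configurable via
  `bn_from_layer`) and is omitted on the innermost level, whose spatial
  extent can be a single pixel.
- Tie-break on even image sides: the merge split is at rows/2; the FFT
  center is the fftshift convention (index N//2).
- Degenerate inputs: empty masks, constant rank inputs, shape mismatches
  and out-of-range parameters raise `ValueError` with the offending value.

## Known limitations

- Phantom smoothness compresses the artifact-SSIM range; absolute SSIM and
  bias values are not comparable to clinical numbers, only their orderings.
- The severity-of-VOI-atrophy artifact bias has the opposite sign on
  phantoms than in a segmentation-based clinical pipeline (see above).
- The numpy networks are CPU-bound and intended for the desk-scale
  configuration; a full 47,872-pair, 100-epoch run is architecturally
  supported but not a practical target for this implementation.
- Likert ratings are handled only as integer vectors for kappa; no observer
  model is provided.
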