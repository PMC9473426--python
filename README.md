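# motioncorr

Motion artifacts from patient movement during 3-D T1-weighted MRI corrupt
automated atrophy measurements: voxel-based-morphometry (VBM) tools that
score hippocampal atrophy as Z-scores against a normal-control database can
misreport atrophy when the input image contains ghosting.  `motioncorr` is
a testbed for that problem.  It simulates motion artifacts by direct
k-space manipulation, trains a Pix2Pix conditional GAN (U-Net generator +
PatchGAN discriminator, with a plain U-Net/MSE baseline) to remove them,
scores atrophy with a normative Z-map surrogate, and quantifies how much of
the scoring damage the correction repairs — all on synthetic brain
phantoms, so the entire pipeline runs on one CPU with no data downloads.

It is aimed at medical-imaging researchers who want a controlled,
fully reproducible environment for artifact/correction experiments rather
than a clinical tool.

## The model in brief

**Artifact simulation.**  For a slice `I` and motion condition (RA, KI):
rotate `I` by ±RA about its center, Fourier-transform both copies
(centered, orthonormal), zero every KI-th phase-encode row of each spectrum
(DC row exempt), merge the top half of the left-rotated spectrum with the
bottom half of the right-rotated one, and take the magnitude of the inverse
transform.  The trained grid is RA ∈ {0, 1, 2, 3}° × KI ∈ {none, 10, 20,
30} px (16 conditions); 1.5°_25 and 2.5°_15 are held out to test
generalization.  (0°, none) is an exact identity.

**Correction.**  Pix2Pix: a U-Net generator (stride-2 4×4 convolutions,
skip connections, tanh output) trained with `L_G = BCE(D(x, G(x)) → true) +
λ·‖G(x) − y‖₁`, λ = 100, against a PatchGAN discriminator that classifies
32×32 patch pairs (64 pairs per 256×256 image) plus a global head, both by
two-class softmax.  Adam, alternating D/G updates.  The baseline is the
same U-Net trained alone with MSE.

**Atrophy scoring.**  Against a control cohort's per-voxel mean μ and SD σ,
a patient's Z-map is `Z = (μ − v)/σ` (positive = apparent loss), summarized
as *severity of VOI atrophy* (mean Z over the hippocampal VOI), *extent of
GM atrophy* (% of gray-matter voxels with Z > 2) and *extent of VOI
atrophy* (% of VOI voxels with Z > 2).

**Agreement.**  SSIM for image fidelity; Bland-Altman mean bias with
±1.96·SD limits of agreement and Spearman's ρ for score agreement; linearly
weighted Cohen's κ for ordinal rating agreement.

## Worked example

```python
from motioncorr import phantom, kspace, evalstats

vol = phantom.generate_phantom_volume(seed=1, n_slices=3, shape=(256, 256))
sl = vol.slices[1]
for ra, ki in [(0, None), (1, 30), (2, 20), (3, 10), (1.5, 25), (2.5, 15)]:
    art = kspace.simulate_motion(sl, kspace.MotionPattern(ra, ki))
    print(f"{kspace.MotionPattern(ra, ki).label:>7}  "
          f"SSIM = {evalstats.ssim(art, sl):.4f}")
```

prints

```
 0_none  SSIM = 1.0000
   1_30  SSIM = 0.9120
   2_20  SSIM = 0.8447
   3_10  SSIM = 0.7305
 1.5_25  SSIM = 0.8163
 2.5_15  SSIM = 0.6749
```

— the no-motion condition is bit-exact (SSIM 1.0) and fidelity falls
strictly as the rotation grows or the zero-fill interval shrinks.

A complete desk-scale experiment (8 training phantoms × 2 slices × 16
conditions = 256 pairs at 64×64, 20 epochs) is what the acceptance tests
run; on held-out phantoms it produces

```
condition   artifact   U-Net   Pix2Pix     (mean SSIM vs original)
0_none        1.0000   0.9541   0.9789
1_30          0.8924   0.9514   0.9795
2_20          0.8845   0.9503   0.9787
3_10          0.8694   0.9485   0.9770
1.5_25        0.9665   0.9519   0.9780
2.5_15        0.8795   0.9497   0.9782
```

so the Pix2Pix correction beats the artifact input on every motion-bearing
condition — including the two it never saw in training — and beats the
U-Net baseline everywhere, while the mean absolute Bland-Altman bias of the
atrophy scores against the originals shrinks after correction (severity of
VOI atrophy 0.32 → 0.15, extent of GM atrophy 7.5 → 5.1, extent of VOI
atrophy 2.4 → 1.3 on the same cohort).

The same pipeline is scriptable from the shell:

```sh
motioncorr phantom --seed 1 --n-slices 8 --side 64 --out scratch/ph
motioncorr simulate --image scratch/ph/phantom_image.nii --ra 2 --ki 20 \
    --out scratch/artifact.nii
motioncorr run-all --seed 0 --out scratch/demo   # end-to-end demo
```

Every run directory contains the resolved `config.yaml`, the package
version, training logs, the report tables (`table_ssim.csv`,
`table_agreement.csv`) and Bland-Altman plots.

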