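"""Synthetic sagittal-brain phantoms with a parametrically atrophiable VOI.

A phantom volume is a stack of 2-D slices built from smooth analytic shapes:
an elliptical "head" of soft tissue, an elliptical gray-matter (GM) band, a
dark ventricle, and two bright hippocampus-like blobs that together form the
volume of interest (VOI).  Per-volume anatomy is jittered with a seeded RNG
so a cohort of phantoms has non-zero between-subject variance, which a
normative (mean/SD) model needs.

Atrophy is a single scalar in [0, 1] that shrinks the VOI blobs in both
amplitude and radius, producing a continuous, monotone, recoverable loss of
VOI intensity while leaving tissue outside the VOI untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["PhantomVolume", "generate_phantom_volume", "inject_atrophy",
           "save_volume"]

# Fractional positions/sizes of the anatomy, relative to (rows, cols).
_HEAD_AX = (0.42, 0.36)          # head ellipse semi-axes
_GM_AX = (0.34, 0.28)            # outer edge of the GM band
_GM_WIDTH = 0.10                 # band thickness
_VENTRICLE_AX = (0.10, 0.08)
_VOI_CENTERS = ((0.62, 0.40), (0.62, 0.60))   # two hippocampal blobs (r, c)
_VOI_SIGMA = 0.045               # blob Gaussian width
_VOI_MASK_RADIUS = 0.055         # binary VOI disk radius
_ATROPHY_AMP_DROP = 0.70         # amplitude multiplier at full atrophy: 1-0.70
_ATROPHY_RAD_DROP = 0.35         # sigma multiplier at full atrophy: 1-0.35

_TISSUE, _GM_LEVEL, _VOI_AMP = 0.35, 0.55, 0.45


@dataclass(frozen=True)
class PhantomVolume:
    """A stack of co-registered phantom slices with GM and VOI masks."""

    slices: np.ndarray          # (n_slices, rows, cols), float64 in [0, 1]
    gm_mask: np.ndarray         # (n_slices, rows, cols), bool
    voi_mask: np.ndarray        # (n_slices, rows, cols), bool; subset of gm
    atrophy_level: float
    seed: int
    shape: tuple[int, int] = field(default=(0, 0))
    noise_sd: float = 0.02
    white_noise_sd: float = 0.002

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


def _grid(rows: int, cols: int):
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    return r, c


def _ellipse(r, c, center, axes, sharpness=6.0):
    """Soft-edged ellipse indicator in [0, 1]."""
    d = np.sqrt(((r - center[0]) / axes[0]) ** 2
                + ((c - center[1]) / axes[1]) ** 2)
    arg = np.clip(sharpness * (d - 1.0) * max(axes), -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(arg))


def _render_slice(rows: int, cols: int, z_scale: float, jitter: dict,
                  atrophy_level: float):
    r, c = _grid(rows, cols)
    center = (rows / 2.0, cols / 2.0)
    s = z_scale * jitter["size"]

    head = _ellipse(r, c, center, (rows * _HEAD_AX[0] * s, cols * _HEAD_AX[1] * s))
    gm_out = _ellipse(r, c, center, (rows * _GM_AX[0] * s, cols * _GM_AX[1] * s))
    gm_in = _ellipse(r, c, center, (rows * (_GM_AX[0] - _GM_WIDTH) * s,
                                    cols * (_GM_AX[1] - _GM_WIDTH) * s))
    gm_band = gm_out - gm_in
    vent = _ellipse(r, c, center, (rows * _VENTRICLE_AX[0] * s,
                                   cols * _VENTRICLE_AX[1] * s))

    img = _TISSUE * head + _GM_LEVEL * jitter["gm"] * np.clip(gm_band, 0, 1)
    img -= 0.30 * vent

    amp = _VOI_AMP * jitter["voi"] * (1.0 - _ATROPHY_AMP_DROP * atrophy_level)
    sig0 = _VOI_SIGMA * min(rows, cols) * s
    sig = sig0 * (1.0 - _ATROPHY_RAD_DROP * atrophy_level)
    voi_mask = np.zeros((rows, cols), dtype=bool)
    for (fr, fc) in _VOI_CENTERS:
        cr, cc = fr * rows, fc * cols
        d2 = (r - cr) ** 2 + (c - cc) ** 2
        img += amp * np.exp(-d2 / (2.0 * sig ** 2))
        voi_mask |= d2 <= (_VOI_MASK_RADIUS * min(rows, cols) * s) ** 2

    gm_mask = (np.clip(gm_band, 0, 1) > 0.5) | voi_mask
    img = np.clip(img, 0.0, 1.0)
    return img, gm_mask, voi_mask, head > 0.5


def _jitter_params(rng: np.random.Generator) -> dict:
    return {
        "size": 1.0 + 0.04 * rng.standard_normal(),
        "gm": 1.0 + 0.06 * rng.standard_normal(),
        "voi": 1.0 + 0.06 * rng.standard_normal(),
        "noise_seed": int(rng.integers(0, 2 ** 31 - 1)),
    }


def generate_phantom_volume(seed: int, n_slices: int = 176,
                            shape: tuple[int, int] = (256, 256),
                            atrophy_level: float = 0.0,
                            noise_sd: float = 0.02,
                            white_noise_sd: float = 0.002) -> PhantomVolume:
    """Generate one deterministic phantom volume.

    Parameters
    ----------
    seed
        Seeds both the per-volume anatomical jitter and the pixel noise;
        identical (seed, parameters) give a bit-identical volume.
    n_slices, shape
        Stack size and in-plane matrix (rows, cols).
    atrophy_level
        0 = no atrophy; 1 = the VOI blobs at their configured intensity and
        radius floor.  VOI mean intensity decreases strictly with the level.
    noise_sd
        SD of the spatially smooth (Gaussian-filtered, sigma 1.5 px)
        intra-head intensity field emulating anatomical variability.
    white_noise_sd
        SD of uncorrelated per-pixel acquisition noise.
    """
    rows, cols = shape
    if n_slices <= 0 or rows <= 0 or cols <= 0:
        raise ValueError(f"non-positive dimensions: {n_slices=}, {shape=}")
    if not 0.0 <= atrophy_level <= 1.0:
        raise ValueError(f"atrophy_level must be in [0, 1], got {atrophy_level}")

    rng = np.random.default_rng(seed)
    jitter = _jitter_params(rng)
    noise_rng = np.random.default_rng(jitter["noise_seed"])

    slices = np.empty((n_slices, rows, cols))
    gm = np.empty((n_slices, rows, cols), dtype=bool)
    voi = np.empty((n_slices, rows, cols), dtype=bool)
    # Through-slice profile: structures shrink toward the stack edges.
    zs = np.linspace(-1.0, 1.0, n_slices) if n_slices > 1 else np.zeros(1)
    for i, z in enumerate(zs):
        z_scale = np.sqrt(max(1.0 - 0.4 * z * z, 1e-3))
        img, g, v, head = _render_slice(rows, cols, z_scale, jitter,
                                        atrophy_level)
        if noise_sd > 0:
            field = ndimage.gaussian_filter(
                noise_rng.standard_normal((rows, cols)), 1.5)
            img = img + noise_sd * (field / field.std()) * head
        if white_noise_sd > 0:
            img = img + white_noise_sd * noise_rng.standard_normal((rows, cols))
        slices[i] = np.clip(img, 0.0, 1.0)
        gm[i], voi[i] = g, v
    return PhantomVolume(slices=slices, gm_mask=gm, voi_mask=voi,
                         atrophy_level=float(atrophy_level), seed=int(seed),
                         shape=(rows, cols), noise_sd=noise_sd,
                         white_noise_sd=white_noise_sd)


def inject_atrophy(volume: PhantomVolume, level: float) -> PhantomVolume:
    """Return the same phantom regenerated at a new atrophy level.

    Regeneration reuses the volume's seed and dimensions, so tissue outside
    the VOI is reproduced exactly; only the VOI blobs change.  ``level=0``
    returns a volume identical to ``generate_phantom_volume(seed, ...)``.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"atrophy level must be in [0, 1], got {level}")
    return generate_phantom_volume(volume.seed, volume.n_slices,
                                   volume.shape, atrophy_level=level,
                                   noise_sd=volume.noise_sd,
                                   white_noise_sd=volume.white_noise_sd)


def voi_mean_intensity(volume: PhantomVolume) -> float:
    """Mean image intensity over the VOI mask (diagnostic)."""
    return float(volume.slices[volume.voi_mask].mean())


def save_volume(volume: PhantomVolume, out_dir: str | Path,
                stem: str = "phantom", png: bool = False) -> dict:
    """Write the volume, its masks (NIfTI) and a JSON parameter sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)

    def _nii(arr, name):
        p = out / f"{stem}_{name}.nii"
        nib.save(nib.Nifti1Image(np.transpose(arr, (1, 2, 0)).astype(np.float32),
                                 aff), p)
        return str(p)

    paths = {
        "image": _nii(volume.slices, "image"),
        "gm_mask": _nii(volume.gm_mask.astype(np.uint8), "gm"),
        "voi_mask": _nii(volume.voi_mask.astype(np.uint8), "voi"),
    }
    if png:
        import imageio.v3 as iio
        png_dir = out / f"{stem}_png"
        png_dir.mkdir(exist_ok=True)
        for i, sl in enumerate(volume.slices):
            iio.imwrite(png_dir / f"slice_{i:03d}.png",
                        (np.clip(sl, 0, 1) * 65535).astype(np.uint16))
        paths["png_dir"] = str(png_dir)
    sidecar = {"seed": volume.seed, "n_slices": volume.n_slices,
               "shape": list(volume.shape),
               "atrophy_level": volume.atrophy_level}
    sidecar_path = out / f"{stem}_params.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = str(sidecar_path)
    return paths
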