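"""Simulated MR motion artifacts via k-space manipulation.

The artifact model emulates a subject who moves once during acquisition of a
sagittal slice: the slice is rotated left and right by the same angle, both
versions are Fourier transformed, phase-encode rows of each spectrum are
zeroed at a fixed interval (signal loss from anterior-posterior motion), the
top half of one spectrum is merged with the bottom half of the other, and the
magnitude of the inverse transform is the artifact image.  Larger rotation
angles and smaller zero-fill intervals give stronger ghosting.

A motion condition is a (rotation angle in degrees, zero-fill interval in
pixels) pair; the trained grid is the 16 combinations of angles {0,1,2,3}
and intervals {none,10,20,30}, with {1.5_25, 2.5_15} as held-out test
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .phantom import PhantomVolume

__all__ = [
    "MotionPattern", "PairedSample", "TRAIN_PATTERNS", "TEST_PATTERNS",
    "rotate_image", "fft2c", "ifft2c_mag", "zero_fill_lines", "merge_halves",
    "simulate_motion", "build_paired_dataset", "nominal_pair_count",
]


@dataclass(frozen=True)
class MotionPattern:
    """One artifact condition: rotation angle (deg) and k-space interval (px).

    ``kspace_interval_px`` is the spacing between zeroed phase-encode rows;
    ``None`` (or 0) means no rows are zeroed.
    """

    rotation_angle_deg: float
    kspace_interval_px: int | None

    def __post_init__(self):
        if self.rotation_angle_deg < 0:
            raise ValueError("rotation angle must be >= 0")
        ki = self.kspace_interval_px
        if ki is not None and ki < 0:
            raise ValueError("k-space interval must be positive or None")

    @property
    def is_identity(self) -> bool:
        return self.rotation_angle_deg == 0 and not self.kspace_interval_px

    @property
    def label(self) -> str:
        ki = "none" if not self.kspace_interval_px else str(self.kspace_interval_px)
        ra = self.rotation_angle_deg
        ra_s = str(int(ra)) if float(ra).is_integer() else str(ra)
        return f"{ra_s}_{ki}"


#: The 4x4 grid of trained conditions: angles 0-3 deg x intervals none/10/20/30.
TRAIN_PATTERNS: tuple[MotionPattern, ...] = tuple(
    MotionPattern(ra, ki)
    for ra in (0.0, 1.0, 2.0, 3.0)
    for ki in (None, 10, 20, 30)
)

#: Evaluation conditions: four trained plus two held-out (1.5_25, 2.5_15).
TEST_PATTERNS: tuple[MotionPattern, ...] = (
    MotionPattern(0.0, None), MotionPattern(1.0, 30), MotionPattern(2.0, 20),
    MotionPattern(3.0, 10), MotionPattern(1.5, 25), MotionPattern(2.5, 15),
)


@dataclass(frozen=True)
class PairedSample:
    """An (artifact, original) training/evaluation image pair."""

    artifact: np.ndarray
    original: np.ndarray
    pattern: MotionPattern
    volume_id: int
    slice_index: int

    def __post_init__(self):
        if self.artifact.shape != self.original.shape:
            raise ValueError("artifact and original must share a shape")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image center (bilinear, zero fill, shape preserved)."""
    img = _check_image(img)
    if angle_deg == 0:
        return img.copy()
    return ndimage.rotate(img, angle_deg, reshape=False, order=1,
                          mode="constant", cval=0.0, prefilter=False)


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D FFT (DC at the grid center)."""
    img = np.asarray(img)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (complex output)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))


def ifft2c_mag(k: np.ndarray) -> np.ndarray:
    """Magnitude of the inverse centered FFT.

    Merged spectra are not Hermitian-symmetric, so the inverse transform is
    complex; its magnitude is the reconstructed image, as in standard MR
    magnitude reconstruction.
    """
    return np.abs(ifft2c(k))


def zero_fill_lines(k: np.ndarray, interval_px: int | None,
                    exempt_dc: bool = True, offset: int = 0) -> np.ndarray:
    """Zero phase-encode rows of a centered spectrum at a fixed interval.

    Row indices are taken in DC-at-origin (unshifted) coordinates: rows with
    index ≡ ``offset`` (mod ``interval_px``) are zeroed, and the DC row
    (index 0) is exempted by default so global contrast survives.  For a
    256-row spectrum with interval 10 this zeroes 25 rows.  ``None`` or 0
    returns the input unchanged.
    """
    k = np.asarray(k)
    if interval_px is None or interval_px == 0:
        return k.copy()
    if interval_px < 0:
        raise ValueError("interval must be positive, 0 or None")
    rows = k.shape[0]
    unshifted_idx = np.arange(rows)
    hit = (unshifted_idx - offset) % interval_px == 0
    if exempt_dc:
        hit &= unshifted_idx != 0
    # Map DC-at-origin rows to their centered positions.
    centered_rows = (unshifted_idx[hit] + rows // 2) % rows
    out = k.copy()
    out[centered_rows, :] = 0.0
    return out


def merge_halves(k_left: np.ndarray, k_right: np.ndarray) -> np.ndarray:
    """Top half rows from ``k_left``, bottom half rows from ``k_right``."""
    if k_left.shape != k_right.shape:
        raise ValueError(f"shape mismatch: {k_left.shape} vs {k_right.shape}")
    rows = k_left.shape[0]
    out = np.empty_like(k_left)
    out[: rows // 2] = k_left[: rows // 2]
    out[rows // 2:] = k_right[rows // 2:]
    return out


def simulate_motion(img: np.ndarray, pattern: MotionPattern) -> np.ndarray:
    """Apply the full artifact pipeline for one motion condition.

    The identity condition (angle 0, interval none) returns the input exactly
    (no interpolation or transform round-trip), matching an acquisition with
    no motion.  Otherwise: rotate by ±angle, transform both, zero-fill both,
    merge top/bottom halves (left rotation supplies the top), and return the
    magnitude of the inverse transform.
    """
    img = _check_image(img)
    if pattern.is_identity:
        return img.copy()
    left = rotate_image(img, +pattern.rotation_angle_deg)
    right = rotate_image(img, -pattern.rotation_angle_deg)
    k_left = zero_fill_lines(fft2c(left), pattern.kspace_interval_px)
    k_right = zero_fill_lines(fft2c(right), pattern.kspace_interval_px)
    merged = merge_halves(k_left, k_right)
    return ifft2c_mag(merged)


def nominal_pair_count(n_volumes: int, n_slices: int, n_patterns: int,
                       stride: int) -> float:
    """Nominal dataset size ``n_volumes * n_slices * n_patterns / stride``.

    This is the headline count for a cohort (one pair per retained slice and
    condition, with 1/stride of slices retained); it is exact when
    ``n_slices`` is divisible by ``stride``.
    """
    return n_volumes * n_slices * n_patterns / stride


def build_paired_dataset(volumes: Sequence[PhantomVolume],
                         patterns: Iterable[MotionPattern] = TRAIN_PATTERNS,
                         slice_stride: int = 3) -> list[PairedSample]:
    """Create (artifact, original) pairs for every retained slice x pattern.

    Every ``slice_stride``-th slice starting at index 0 is retained, so each
    volume contributes ``ceil(n_slices / slice_stride)`` slices.
    """
    patterns = list(patterns)
    if not volumes:
        raise ValueError("volume list is empty")
    if not patterns:
        raise ValueError("pattern list is empty")
    if slice_stride < 1:
        raise ValueError("slice_stride must be >= 1")
    pairs: list[PairedSample] = []
    for vol_id, vol in enumerate(volumes):
        for idx in range(0, vol.n_slices, slice_stride):
            original = vol.slices[idx]
            for pat in patterns:
                pairs.append(PairedSample(
                    artifact=simulate_motion(original, pat),
                    original=original.copy(), pattern=pat,
                    volume_id=vol_id, slice_index=idx))
    return pairs
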