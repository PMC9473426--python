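"""Voxel-based morphometry Z-score atrophy indices against a normative model.

The scorer mirrors the clinical VBM workflow: a normative model holds the
per-voxel mean and SD of a normal-control cohort; a patient volume is
converted to a Z-map, Z = (mean_NC - patient) / SD_NC, so positive Z means
signal loss (atrophy).  Three summary indices are reported:

- severity of VOI atrophy: mean Z over the hippocampal VOI mask,
- extent of GM atrophy: percent of gray-matter voxels with Z > 2 (strict),
- extent of VOI atrophy: percent of VOI voxels with Z > 2 (strict).

Phantom cohorts are generated co-registered, so no spatial normalization or
segmentation step is needed; registration is the identity by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NormativeModel", "ZMap", "AtrophyScores", "fit_normative_model",
           "compute_zmap", "severity_voi", "extent_gm", "extent_voi",
           "score_volume"]

#: SD floor as a fraction of the intensity range (keeps Z finite).
SD_FLOOR = 1e-6


@dataclass(frozen=True)
class NormativeModel:
    """Per-voxel mean and sample SD of a normal-control cohort."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    n_controls: int


@dataclass(frozen=True)
class ZMap:
    z: np.ndarray
    gm_mask: np.ndarray
    voi_mask: np.ndarray


@dataclass(frozen=True)
class AtrophyScores:
    severity_voi: float
    extent_gm: float
    extent_voi: float


def fit_normative_model(control_volumes) -> NormativeModel:
    """Voxel-wise mean and sample SD (ddof=1) over aligned control volumes.

    ``control_volumes`` is a sequence of arrays (or objects with ``.slices``)
    sharing one shape.  The SD is floored at ``SD_FLOOR`` times the cohort
    intensity range so Z-maps stay finite at zero-variance voxels.
    """
    arrays = [np.asarray(getattr(v, "slices", v), dtype=np.float64)
              for v in control_volumes]
    if len(arrays) < 2:
        raise ValueError("need at least 2 control volumes")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("control volumes must share a shape")
    stack = np.stack(arrays)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    rng_span = float(stack.max() - stack.min()) or 1.0
    sd = np.maximum(sd, SD_FLOOR * rng_span)
    return NormativeModel(mean_map=mean, sd_map=sd, n_controls=len(arrays))


def compute_zmap(patient, model: NormativeModel, gm_mask=None,
                 voi_mask=None) -> ZMap:
    """Z = (normal-control mean - patient) / normal-control SD, voxel-wise.

    Positive Z marks voxels darker than the normative mean, i.e. tissue loss.
    Masks default to the patient volume's own masks when it carries them.
    """
    arr = np.asarray(getattr(patient, "slices", patient), dtype=np.float64)
    if arr.shape != model.mean_map.shape:
        raise ValueError(f"shape mismatch: patient {arr.shape} vs "
                         f"model {model.mean_map.shape}")
    if gm_mask is None:
        gm_mask = getattr(patient, "gm_mask", None)
    if voi_mask is None:
        voi_mask = getattr(patient, "voi_mask", None)
    if gm_mask is None or voi_mask is None:
        raise ValueError("gm_mask and voi_mask are required")
    z = (model.mean_map - arr) / model.sd_map
    return ZMap(z=z, gm_mask=np.asarray(gm_mask, dtype=bool),
                voi_mask=np.asarray(voi_mask, dtype=bool))


def severity_voi(zmap: ZMap, positive_only: bool = False) -> float:
    """Mean Z over the VOI (``positive_only`` averages max(Z, 0) instead)."""
    if not zmap.voi_mask.any():
        raise ValueError("VOI mask is empty")
    z = zmap.z[zmap.voi_mask]
    if positive_only:
        z = np.maximum(z, 0.0)
    return float(z.mean())


def extent_gm(zmap: ZMap) -> float:
    """Percent of gray-matter voxels with Z strictly above 2."""
    if not zmap.gm_mask.any():
        raise ValueError("GM mask is empty")
    z = zmap.z[zmap.gm_mask]
    return float(100.0 * np.count_nonzero(z > 2.0) / z.size)


def extent_voi(zmap: ZMap) -> float:
    """Percent of VOI voxels with Z strictly above 2."""
    if not zmap.voi_mask.any():
        raise ValueError("VOI mask is empty")
    z = zmap.z[zmap.voi_mask]
    return float(100.0 * np.count_nonzero(z > 2.0) / z.size)


def score_volume(patient, model: NormativeModel, gm_mask=None,
                 voi_mask=None) -> AtrophyScores:
    """All three indices for one patient volume."""
    zm = compute_zmap(patient, model, gm_mask=gm_mask, voi_mask=voi_mask)
    return AtrophyScores(severity_voi=severity_voi(zm),
                         extent_gm=extent_gm(zm),
                         extent_voi=extent_voi(zm))
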