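"""Brain volumes, head-size normalization and WMH lesion load.

Native GM/WM volumes come from the soft segmentation (summing tissue
probabilities times voxel volume).  A skull-based scaling factor — supplied
per subject, describing brain size relative to skull size — converts native
volumes to normalized brain volumes (NBVs).  Because lesions are often
misclassified as GM by intensity-driven segmentation, the normalized GM
volume falling inside the WMH mask is reassigned from GM to WM.  WMH lesion
load is the lesion volume as a percentage of whole brain volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import ConfigError, ShapeError
from .images import SubjectImaging, VoxelVolume, check_same_grid


@dataclass
class VolumeSummary:
    native_brain_ml: float
    gm_nbv_ml: float
    wm_nbv_ml: float
    whole_nbv_ml: float
    wmh_ml: float
    wmh_lesion_load_pct: float
    lacune_count: int


def soft_volumes(tpm_gm: VoxelVolume, tpm_wm: VoxelVolume) -> Tuple[float, float, float]:
    """Native-space (gm_ml, wm_ml, brain_ml) from the soft segmentation."""
    check_same_grid({"tpm_gm": tpm_gm, "tpm_wm": tpm_wm})
    vml = tpm_gm.voxel_ml
    gm_ml = float(tpm_gm.values.sum() * vml)
    wm_ml = float(tpm_wm.values.sum() * vml)
    return gm_ml, wm_ml, gm_ml + wm_ml


def normalize_volumes(gm_ml: float, wm_ml: float, scaling_factor: float) -> Tuple[float, float]:
    """Scale native volumes by the skull-based factor to obtain NBVs."""
    if scaling_factor <= 0:
        raise ConfigError(f"scaling_factor must be positive, got {scaling_factor}")
    return gm_ml * scaling_factor, wm_ml * scaling_factor


def reassign_wmh_gm(
    gm_nbv: float,
    wm_nbv: float,
    tpm_gm: VoxelVolume,
    wmh_mask: VoxelVolume,
    scaling_factor: float,
) -> Tuple[float, float]:
    """Move the normalized GM volume inside the WMH mask from GM to WM.

    Conserves ``gm + wm`` exactly.
    """
    check_same_grid({"tpm_gm": tpm_gm, "wmh_mask": wmh_mask})
    if scaling_factor <= 0:
        raise ConfigError(f"scaling_factor must be positive, got {scaling_factor}")
    inside = wmh_mask.values == 1
    v = float(tpm_gm.values[inside].sum() * tpm_gm.voxel_ml * scaling_factor)
    if v > gm_nbv + 1e-9:
        raise ShapeError(
            f"GM volume within WMH ({v:.3f} ml) exceeds total GM NBV ({gm_nbv:.3f} ml)"
        )
    return gm_nbv - v, wm_nbv + v


def wmh_volume_ml(wmh_mask: VoxelVolume) -> float:
    """Lesion volume from the binary mask (hard contour) in ml."""
    return float(wmh_mask.values.sum() * wmh_mask.voxel_ml)


def wmh_lesion_load(wmh_ml: float, brain_ml: float) -> float:
    """WMH lesion volume as a percentage of whole brain volume."""
    if brain_ml <= 0:
        raise ConfigError("brain volume must be positive to form a lesion load")
    return 100.0 * wmh_ml / brain_ml


def summarize_subject_volumes(
    subject: SubjectImaging, lesion_load_denominator: str = "native"
) -> VolumeSummary:
    """All volumetric markers for one subject.

    ``lesion_load_denominator`` chooses the whole-brain volume used for the
    lesion load: the native soft-segmentation volume (default) or the
    normalized volume.
    """
    if lesion_load_denominator not in ("native", "normalized"):
        raise ConfigError("lesion_load_denominator must be 'native' or 'normalized'")
    gm_ml, wm_ml, brain_ml = soft_volumes(subject.tpm_gm, subject.tpm_wm)
    gm_nbv, wm_nbv = normalize_volumes(gm_ml, wm_ml, subject.scaling_factor)
    gm_nbv, wm_nbv = reassign_wmh_gm(
        gm_nbv, wm_nbv, subject.tpm_gm, subject.wmh_mask, subject.scaling_factor
    )
    whole_nbv = gm_nbv + wm_nbv
    wmh_ml = wmh_volume_ml(subject.wmh_mask)
    denom = brain_ml if lesion_load_denominator == "native" else whole_nbv
    load = wmh_lesion_load(wmh_ml, denom)
    return VolumeSummary(
        native_brain_ml=brain_ml,
        gm_nbv_ml=gm_nbv,
        wm_nbv_ml=wm_nbv,
        whole_nbv_ml=whole_nbv,
        wmh_ml=wmh_ml,
        wmh_lesion_load_pct=load,
        lacune_count=subject.lacune_count,
    )
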