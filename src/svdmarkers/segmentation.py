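"""Hard tissue segmentation, white-matter analysis masks and DTI voxel cleaning.

The segmentation assigns each in-brain voxel to the tissue class (GM, WM, CSF)
with the highest probability, then overwrites lesion voxels with a dedicated
WMH label.  The NAWM mask is the set of WM-labelled voxels; the all-WM mask
adds the WMH voxels.  Before histogramming, voxels with MD above the CSF
misclassification threshold or with spurious FA above 1 are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import EmptyMaskError
from .images import VoxelVolume, check_same_grid

#: CSF-misclassification diffusivity threshold (mm^2/s); strictly-above removed.
MD_CLEAN_THRESHOLD = 0.0026
#: Spurious-anisotropy threshold; strictly-above removed.
FA_CLEAN_THRESHOLD = 1.0
#: All tissue probabilities below this mark a voxel as outside the brain.
BACKGROUND_TPM_THRESHOLD = 0.01


class TissueLabel(IntEnum):
    BACKGROUND = 0
    GM = 1
    WM = 2
    CSF = 3
    WMH = 4


@dataclass
class TissueLabelVolume:
    """Hard segmentation: one :class:`TissueLabel` per voxel."""

    labels: np.ndarray
    voxel_mm: tuple

    def count(self, label: TissueLabel) -> int:
        return int(np.sum(self.labels == int(label)))


@dataclass
class AnalysisMaskSet:
    """NAWM and all-WM binary analysis masks (NAWM is a subset of all-WM)."""

    nawm_mask: np.ndarray
    allwm_mask: np.ndarray
    voxel_mm: tuple

    def mask(self, tissue_class: str) -> np.ndarray:
        if tissue_class == "nawm":
            return self.nawm_mask
        if tissue_class == "wm":
            return self.allwm_mask
        raise KeyError(f"unknown tissue class {tissue_class!r}; use 'nawm' or 'wm'")


@dataclass
class CleanedValues:
    """FA/MD value collections within one mask after voxel cleaning."""

    fa_values: np.ndarray
    md_values: np.ndarray
    n_removed_md: int
    n_removed_fa: int
    n_input: int


def hard_segment(
    tpm_gm: VoxelVolume,
    tpm_wm: VoxelVolume,
    tpm_csf: VoxelVolume,
    wmh_mask: VoxelVolume,
) -> TissueLabelVolume:
    """Assign each voxel to its most probable tissue class, with WMH override.

    Ties between probabilities are broken by the fixed priority GM > WM > CSF.
    Voxels where all three probabilities fall below
    :data:`BACKGROUND_TPM_THRESHOLD` are background.  Any voxel with
    ``wmh_mask == 1`` is assigned the WMH label regardless of the
    probabilities.
    """
    check_same_grid(
        {"tpm_gm": tpm_gm, "tpm_wm": tpm_wm, "tpm_csf": tpm_csf, "wmh_mask": wmh_mask}
    )
    stacked = np.stack([tpm_gm.values, tpm_wm.values, tpm_csf.values])
    # argmax over axis 0 takes the first maximum: order GM, WM, CSF encodes
    # the tie-break priority.
    winner = np.argmax(stacked, axis=0)
    labels = np.choose(
        winner, [int(TissueLabel.GM), int(TissueLabel.WM), int(TissueLabel.CSF)]
    ).astype(np.int16)
    background = np.all(stacked < BACKGROUND_TPM_THRESHOLD, axis=0)
    labels[background] = int(TissueLabel.BACKGROUND)
    labels[wmh_mask.values == 1] = int(TissueLabel.WMH)
    return TissueLabelVolume(labels=labels, voxel_mm=tpm_gm.voxel_mm)


def make_masks(labels: TissueLabelVolume) -> AnalysisMaskSet:
    """Build the NAWM and all-WM masks from a hard segmentation."""
    nawm = labels.labels == int(TissueLabel.WM)
    allwm = nawm | (labels.labels == int(TissueLabel.WMH))
    return AnalysisMaskSet(nawm_mask=nawm, allwm_mask=allwm, voxel_mm=labels.voxel_mm)


def clean_dti_voxels(
    fa: VoxelVolume,
    md: VoxelVolume,
    mask: np.ndarray,
    md_threshold: float = MD_CLEAN_THRESHOLD,
    fa_threshold: float = FA_CLEAN_THRESHOLD,
    joint: bool = True,
) -> CleanedValues:
    """Collect FA/MD values within ``mask``, removing threshold-failing voxels.

    A voxel is removed when ``md > md_threshold`` (likely CSF partial volume)
    or ``fa > fa_threshold`` (spurious anisotropy); both inequalities are
    strict.  With ``joint=True`` (default) a voxel failing either rule leaves
    both value collections, keeping the FA and MD histograms on the same voxel
    support; with ``joint=False`` each collection applies only its own rule.
    """
    check_same_grid({"fa": fa, "md": md})
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fa.shape:
        raise EmptyMaskError(
            f"mask shape {mask.shape} does not match volume shape {fa.shape}"
        )
    if not mask.any():
        raise EmptyMaskError("no voxels in tissue class")
    fa_in = fa.values[mask]
    md_in = md.values[mask]
    bad_md = md_in > md_threshold
    bad_fa = fa_in > fa_threshold
    if joint:
        keep = ~(bad_md | bad_fa)
        fa_vals = fa_in[keep]
        md_vals = md_in[keep]
    else:
        fa_vals = fa_in[~bad_fa]
        md_vals = md_in[~bad_md]
    return CleanedValues(
        fa_values=fa_vals,
        md_values=md_vals,
        n_removed_md=int(bad_md.sum()),
        n_removed_fa=int(bad_fa.sum()),
        n_input=int(mask.sum()),
    )
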