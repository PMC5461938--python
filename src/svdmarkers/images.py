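"""In-memory containers for coregistered scalar volumes and per-subject imaging.

All volumes in one subject live on a common grid (the inputs are assumed
pre-coregistered); the affine is a plain voxel-size scaling, which is all the
histogram and volumetric operations need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

from .errors import ShapeError

#: Allowed volume kinds. FA is dimensionless, MD is in mm^2/s, TPM is a
#: tissue probability, mask is binary.
VOLUME_KINDS = ("FA", "MD", "TPM", "mask")


@dataclass
class VoxelVolume:
    """A 3-D scalar lattice with voxel dimensions in mm.

    Parameters
    ----------
    values
        3-D float array.
    voxel_mm
        Voxel edge lengths in mm, all positive.
    kind
        One of ``FA``, ``MD``, ``TPM``, ``mask``.
    """

    values: np.ndarray
    voxel_mm: Tuple[float, float, float]
    kind: str = "FA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ShapeError(f"VoxelVolume values must be 3-D, got {self.values.ndim}-D")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ShapeError(f"voxel_mm must be three positive lengths, got {self.voxel_mm}")
        if self.kind not in VOLUME_KINDS:
            raise ShapeError(f"unknown volume kind {self.kind!r}")
        if self.kind == "mask":
            vals = np.unique(self.values)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ShapeError("mask volume must contain only 0 and 1")
        elif self.kind == "TPM":
            if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
                raise ShapeError("TPM volume must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.voxel_mm)) / 1000.0

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_mm) + [1.0])
        return nib.Nifti1Image(self.values.astype(np.float64), affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, kind: str) -> "VoxelVolume":
        img = nib.load(str(path))
        voxel_mm = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), voxel_mm, kind)


def check_same_grid(named_volumes: dict) -> None:
    """Raise :class:`ShapeError` naming the first volume off the common grid."""
    items = list(named_volumes.items())
    ref_name, ref = items[0]
    for name, vol in items[1:]:
        if vol.shape != ref.shape:
            raise ShapeError(
                f"volume {name!r} has shape {vol.shape}, expected {ref.shape} (as {ref_name!r})"
            )
        if not np.allclose(vol.voxel_mm, ref.voxel_mm):
            raise ShapeError(
                f"volume {name!r} has voxel_mm {vol.voxel_mm}, expected {ref.voxel_mm}"
            )


@dataclass
class SubjectImaging:
    """One subject's coregistered volumes plus scalar imaging covariates.

    ``latent_integrity`` is the generator's ground-truth white-matter-integrity
    scalar (standardized); it is carried for validation only and never enters
    the analysis pipeline.
    """

    subject_id: str
    site_id: int
    fa: VoxelVolume
    md: VoxelVolume
    tpm_gm: VoxelVolume
    tpm_wm: VoxelVolume
    tpm_csf: VoxelVolume
    wmh_mask: VoxelVolume
    lacune_count: int = 0
    scaling_factor: float = 1.0
    latent_integrity: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        check_same_grid(
            {
                "fa": self.fa,
                "md": self.md,
                "tpm_gm": self.tpm_gm,
                "tpm_wm": self.tpm_wm,
                "tpm_csf": self.tpm_csf,
                "wmh_mask": self.wmh_mask,
            }
        )
        if self.lacune_count < 0:
            raise ShapeError("lacune_count must be non-negative")
        if self.scaling_factor <= 0:
            raise ShapeError("scaling_factor must be positive")

    @property
    def tpm_sum(self) -> np.ndarray:
        return self.tpm_gm.values + self.tpm_wm.values + self.tpm_csf.values
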