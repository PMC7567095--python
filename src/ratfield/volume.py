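"""CT volume container with NIfTI I/O.

Voxel values are Hounsfield units; the affine maps voxel indices to world
millimetres.  Only isotropic spacings are produced by this package, matching
the isotropic acquisitions the pipeline targets.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "LabelVolume", "read_nifti", "write_nifti"]

LABEL_AIR = 0
LABEL_BODY = 1
LABEL_BONE = 2
LABEL_BRAIN = 3


@dataclasses.dataclass
class CTVolume:
    data: np.ndarray  # (nx, ny, nz) float, HU
    spacing: float  # mm, isotropic
    origin: np.ndarray  # world position of voxel (0,0,0) centre, mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("HU values must be finite")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.spacing
        aff[:3, 3] = self.origin
        return aff

    def voxel_centres_axis(self, axis: int) -> np.ndarray:
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.spacing


@dataclasses.dataclass
class LabelVolume:
    """Voxel labels (air/body/bone and optionally brain) on a CT grid."""

    labels: np.ndarray  # int8, same shape as source CT
    spacing: float
    origin: np.ndarray

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def write_nifti(vol: CTVolume | LabelVolume, path: str | Path) -> Path:
    data = vol.data if isinstance(vol, CTVolume) else vol.labels
    aff = np.eye(4)
    aff[:3, :3] *= vol.spacing
    aff[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(data), aff)
    nib.save(img, str(path))
    return Path(path)


def read_nifti(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    aff = img.affine
    sp = np.abs(np.diag(aff)[:3])
    if not np.allclose(sp, sp[0], rtol=1e-3):
        raise ValueError("only isotropic NIfTI volumes are supported")
    return CTVolume(np.asarray(img.dataobj, dtype=np.float32), float(sp[0]), aff[:3, 3].copy())
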