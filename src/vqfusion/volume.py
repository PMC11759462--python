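"""The Volume3D container and NIfTI I/O.

A :class:`Volume3D` is one single-modality 3-D intensity grid with voxel
spacing in millimetres and an optional lesion centre in 0-based voxel
coordinates. Prostate mpMRI is strongly anisotropic — in-plane spacing is
much finer than slice spacing — so spacing is carried everywhere and the
slice axis is treated separately by the networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "load_nifti", "save_nifti"]


@dataclass
class Volume3D:
    """Single-modality 3-D image: intensities (X,Y,Z), spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_centre: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D expects a 3-D array, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return replace(self, data=np.asarray(data, dtype=np.float64))


def load_nifti(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data, spacing=tuple(float(z) for z in zooms))


def save_nifti(volume: Volume3D, path: str | Path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
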