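"""Resampling, lesion-centred cropping, intensity normalisation, augmentation.

The pipeline mirrors routine prostate mpMRI preparation: resample every
volume to a common anisotropic grid (default 0.5×0.5×1.5 mm), crop a
fixed-size patch centred on the lesion, rescale intensities to [0, 1], and
(training only) apply one random in-plane flip followed by an in-plane
rotation in [−90°, 90°] — the same spatial transform to both modalities so
their voxelwise correspondence is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "PreprocessSpec", "resample", "crop_patch", "rescale_intensity",
    "augment", "preprocess_case", "read_lesion_sidecar",
]


@dataclass(frozen=True)
class PreprocessSpec:
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 1.5)
    patch_size: tuple[int, int, int] = (128, 128, 8)
    augment: bool = False

    def __post_init__(self):
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target spacing must be positive")
        if any(p <= 0 for p in self.patch_size):
            raise ValueError("patch size must be positive")


def _to_sitk(volume: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(volume.data.transpose(2, 1, 0))  # sitk is (z,y,x)
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    return img


def resample(
    volume: Volume3D,
    target_spacing: tuple[float, float, float],
    is_label: bool = False,
) -> Volume3D:
    """Resample to ``target_spacing`` over the same physical extent.

    Images use cubic B-spline interpolation; label maps nearest-neighbour.
    """
    if volume.spacing is None:
        raise ValueError("volume has no spacing metadata")
    if tuple(volume.spacing) == tuple(target_spacing):
        return Volume3D(volume.data.copy(), spacing=volume.spacing,
                        lesion_centre=volume.lesion_centre)
    img = _to_sitk(volume)
    size_out = [
        max(1, int(round(n * s / t)))
        for n, s, t in zip(volume.shape, volume.spacing, target_spacing)
    ]
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(float(t) for t in target_spacing))
    res.SetSize(size_out)
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(sitk.sitkNearestNeighbor if is_label else sitk.sitkBSpline)
    # output voxel centres near the far edge can fall beyond the last input
    # voxel centre; clamp to the edge value instead of zero-filling
    res.SetUseNearestNeighborExtrapolator(True)
    out = sitk.GetArrayFromImage(res.Execute(img)).transpose(2, 1, 0)
    centre = None
    if volume.lesion_centre is not None:
        centre = tuple(
            int(round(c * s / t))
            for c, s, t in zip(volume.lesion_centre, volume.spacing, target_spacing)
        )
    return Volume3D(np.asarray(out, dtype=np.float64),
                    spacing=tuple(target_spacing), lesion_centre=centre)


def crop_patch(
    volume: Volume3D,
    centre: tuple[int, int, int],
    patch_size: tuple[int, int, int],
) -> tuple[Volume3D, tuple[int, int, int]]:
    """Fixed-size patch centred on ``centre``; out-of-bounds voxels are 0.

    Returns the patch and the offset of its first voxel in the source
    volume's coordinates (may be negative when padding occurred).
    """
    for c, n in zip(centre, volume.shape):
        if not (0 <= c < n):
            raise ValueError(f"centre {centre} outside volume of shape {volume.shape}")
    starts = [c - p // 2 for c, p in zip(centre, patch_size)]
    out = np.zeros(patch_size, dtype=np.float64)
    src_sl, dst_sl = [], []
    for st, p, n in zip(starts, patch_size, volume.shape):
        lo, hi = max(st, 0), min(st + p, n)
        src_sl.append(slice(lo, hi))
        dst_sl.append(slice(lo - st, hi - st))
    out[tuple(dst_sl)] = volume.data[tuple(src_sl)]
    new_centre = tuple(c - st for c, st in zip(centre, starts))
    patch = Volume3D(out, spacing=volume.spacing, lesion_centre=new_centre)
    return patch, tuple(starts)


def rescale_intensity(volume: Volume3D) -> Volume3D:
    """Affine rescale so min → 0 and max → 1; constant volumes become 0."""
    lo, hi = float(volume.data.min()), float(volume.data.max())
    if hi - lo < 1e-30:
        warnings.warn("constant volume: rescale_intensity returning zeros")
        return volume.with_data(np.zeros_like(volume.data))
    return volume.with_data((volume.data - lo) / (hi - lo))


def apply_inplane_transform(
    volume: Volume3D, flip_axis: int | None, angle_deg: float
) -> Volume3D:
    """Flip about an in-plane axis (None = no flip) then rotate in-plane.

    Rotation uses linear interpolation with zero fill and acts only about
    the slice axis, consistent with the anisotropic geometry. With no flip
    and a 0° angle the volume is returned unchanged.
    """
    data = volume.data
    if flip_axis is not None:
        data = np.flip(data, axis=flip_axis)
    if angle_deg != 0.0:
        data = ndimage.rotate(data, angle_deg, axes=(0, 1), reshape=False,
                              order=1, mode="constant", cval=0.0)
    return volume.with_data(data)


def augment(
    pair: tuple[Volume3D, Volume3D],
    seed: int,
) -> tuple[Volume3D, Volume3D]:
    """One random in-plane flip then a rotation drawn from [−90°, 90°].

    The flip axis is vertical or horizontal with equal probability and the
    identical transform is applied to both modalities, preserving their
    voxelwise correspondence.
    """
    t2, adc = pair
    if t2.shape != adc.shape:
        raise ValueError(f"paired shapes differ: {t2.shape} vs {adc.shape}")
    rng = np.random.default_rng(seed)
    flip_axis = int(rng.integers(2))  # 0 = vertical, 1 = horizontal
    angle = float(rng.uniform(-90.0, 90.0))
    return (
        apply_inplane_transform(t2, flip_axis, angle),
        apply_inplane_transform(adc, flip_axis, angle),
    )


def preprocess_case(
    t2: Volume3D,
    adc: Volume3D,
    spec: PreprocessSpec,
    seed: int | None = None,
) -> tuple[Volume3D, Volume3D]:
    """resample → crop about the lesion → rescale → (optional) augment."""
    out = []
    for v in (t2, adc):
        v = resample(v, spec.target_spacing)
        if v.lesion_centre is None:
            raise ValueError("preprocess_case requires a lesion centre")
        patch, _ = crop_patch(v, v.lesion_centre, spec.patch_size)
        out.append(rescale_intensity(patch))
    t2p, adcp = out
    if spec.augment:
        if seed is None:
            raise ValueError("augmentation requires a seed")
        t2p, adcp = augment((t2p, adcp), seed)
    return t2p, adcp


def read_lesion_sidecar(path: str | Path) -> pd.DataFrame:
    """Lesion-centre sidecar CSV: case_id, x, y, z (0-based voxels), label."""
    df = pd.read_csv(path)
    required = {"case_id", "x", "y", "z", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sidecar CSV missing columns: {sorted(missing)}")
    return df
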