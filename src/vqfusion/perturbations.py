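"""Test-time corruption suite: noise, blur, and motion artefact.

Five families over [0,1]-normalised volumes:

* ``gaussian`` — additive zero-mean noise; "level" is the standard
  deviation on the normalised intensity scale.
* ``poisson`` — photon-count noise: each voxel v is replaced by
  Poisson(v·λ)/λ with λ = 1/level², so the relative noise grows with the
  level (level 0 ⇒ identity).
* ``salt_pepper`` — a fraction "level" of voxels, chosen uniformly, is set
  to 0 or 1 with equal probability.
* ``blur`` — per-slice convolution with a 7×7 Gaussian kernel of the given
  variance, reflective boundaries (deterministic).
* ``motion`` — a k-space line-replacement model of within-acquisition
  subject motion: a random subset of in-plane frequency-space lines is
  taken from a rigidly displaced copy of the volume (in-plane translation
  ≤ 3 voxels, rotation ≤ 5°).

The benchmark protocol uses noise levels {1,5,10,15,20,25,30}% for the
three noise families, blur variances {0.1, 1.0, 2.0}, and one motion
setting — 25 corruption settings in total. The "%" semantics for Gaussian
and Poisson noise are a convention of this package (see docs), not a
standard; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "PerturbationSpec", "apply_perturbation", "protocol_grid",
    "NOISE_LEVELS", "BLUR_VARIANCES", "KINDS",
]

NOISE_LEVELS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
BLUR_VARIANCES = (0.1, 1.0, 2.0)
KINDS = ("gaussian", "poisson", "salt_pepper", "blur", "motion", "none")

_MOTION_MAX_TRANSLATION = 3.0   # voxels, in-plane
_MOTION_MAX_ROTATION = 5.0      # degrees, in-plane
_MOTION_LINE_FRACTION = 0.35    # fraction of k-space lines replaced


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str
    level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind '{self.kind}'")
        if self.level < 0:
            raise ValueError("level must be nonnegative")

    @property
    def tag(self) -> str:
        return "none" if self.kind == "none" else f"{self.kind}@{self.level:g}"


def _gaussian_kernel_1d(variance: float, radius: int = 3) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * variance))
    return k / k.sum()


def _blur(data: np.ndarray, variance: float) -> np.ndarray:
    """Separable 7×7 Gaussian blur applied slice by slice."""
    k = _gaussian_kernel_1d(variance)
    out = ndimage.correlate1d(data, k, axis=0, mode="reflect")
    return ndimage.correlate1d(out, k, axis=1, mode="reflect")


def _motion(data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blend in-plane k-space lines with those of a rigidly moved copy."""
    dx, dy = rng.uniform(-_MOTION_MAX_TRANSLATION, _MOTION_MAX_TRANSLATION, size=2)
    angle = rng.uniform(-_MOTION_MAX_ROTATION, _MOTION_MAX_ROTATION)
    moved = ndimage.rotate(data, angle, axes=(0, 1), reshape=False,
                           order=1, mode="nearest")
    moved = ndimage.shift(moved, (dx, dy, 0.0), order=1, mode="nearest")
    f_orig = np.fft.fft2(data, axes=(0, 1))
    f_moved = np.fft.fft2(moved, axes=(0, 1))
    n_lines = data.shape[0]
    replace = rng.random(n_lines) < _MOTION_LINE_FRACTION
    f_orig[replace] = f_moved[replace]
    return np.real(np.fft.ifft2(f_orig, axes=(0, 1)))


def apply_perturbation(volume: Volume3D, spec: PerturbationSpec) -> Volume3D:
    """Corrupt a [0,1]-normalised volume; output stays within [0,1]."""
    data = volume.data
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        raise ValueError("apply_perturbation expects intensities in [0, 1]")
    if spec.kind == "none" or spec.level == 0.0:
        return volume.with_data(data.copy())
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian":
        out = data + rng.normal(0.0, spec.level, size=data.shape)
    elif spec.kind == "poisson":
        lam = 1.0 / spec.level**2
        out = rng.poisson(np.clip(data, 0, 1) * lam) / lam
    elif spec.kind == "salt_pepper":
        out = data.copy()
        n = data.size
        n_hit = int(round(spec.level * n))
        idx = rng.choice(n, size=n_hit, replace=False)
        vals = rng.integers(0, 2, size=n_hit).astype(np.float64)
        out.ravel()[idx] = vals
    elif spec.kind == "blur":
        out = _blur(data, spec.level)
    elif spec.kind == "motion":
        out = _motion(data, rng)
    else:  # pragma: no cover - guarded by PerturbationSpec
        raise ValueError(spec.kind)
    return volume.with_data(np.clip(out, 0.0, 1.0))


def protocol_grid(seed: int = 0) -> list[PerturbationSpec]:
    """The 25-setting benchmark grid: 7+7+7 noise, 3 blur, 1 motion."""
    specs = []
    s = seed
    for kind in ("gaussian", "poisson", "salt_pepper"):
        for level in NOISE_LEVELS:
            specs.append(PerturbationSpec(kind, level, seed=s))
            s += 1
    for var in BLUR_VARIANCES:
        specs.append(PerturbationSpec("blur", var, seed=s))
        s += 1
    specs.append(PerturbationSpec("motion", 1.0, seed=s))
    return specs
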