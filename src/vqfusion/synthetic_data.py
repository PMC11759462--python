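"""Paired pseudo-T2 / pseudo-ADC phantom generator with a domain knob.

Each case is a geometric phantom: an ellipsoidal "gland" with a smooth
random background texture and one ellipsoidal lesion at a random interior
position. Lesion appearance is class-dependent — mean lesion intensity in
the ADC channel decreases strictly with risk grade (emulating diffusion
restriction increasing with aggressiveness), with a smaller parallel trend
in the T2 channel. The ``domain`` knob (A/B) emulates acquisition shift
between scanners (1.5 T vs 3 T style): global contrast scaling, a
different noise floor and a mild in-plane blur — never a change to the
class-conditional ordering or to lesion geometry, so the shift is purely
covariate.

Phantoms are geometric, not anatomically realistic: they exist to exercise
the mechanism (codebooks, fusion, robustness), not to imitate clinical
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume3D, save_nifti

__all__ = [
    "PhantomSpec", "Case", "DEFAULT_CONTRAST", "generate_case",
    "generate_dataset", "write_dataset", "oracle_accuracy",
]

#: Per-class mean lesion intensity by modality. ADC strictly decreases with
#: grade (low > medium > high); T2 follows a smaller parallel trend.
DEFAULT_CONTRAST: dict[str, dict[str, float]] = {
    "t2": {"low": 0.62, "medium": 0.54, "high": 0.46},
    "adc": {"low": 0.75, "medium": 0.55, "high": 0.35},
}

#: Per-domain acquisition style: contrast scale, additive noise s.d. on the
#: [0,1] scale, and in-plane Gaussian blur sigma (voxels).
_DOMAIN_STYLE = {
    "A": {"contrast": 1.00, "noise": 0.02, "blur": 0.0},
    "B": {"contrast": 0.85, "noise": 0.04, "blur": 0.6},
}


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (128, 128, 8)
    class_label: str = "low"
    domain: str = "A"
    seed: int = 0
    contrast: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CONTRAST.items()}
    )
    #: multiplies the class-mean gaps about the "medium" level; 1 = default
    contrast_gap: float = 1.0
    lesion_jitter: float = 0.03   # s.d. of per-case lesion-mean jitter
    #: multiplies the domain's additive noise floor; 0 gives noise-free
    #: "smooth" phantoms for reconstruction benchmarking
    noise_scale: float = 1.0
    #: background texture: amplitude and (in-plane, through-plane) Gaussian
    #: correlation lengths of the smoothed random field, in voxels. Rich
    #: enough that a small codebook cannot reconstruct it faithfully.
    texture_amplitude: float = 0.16
    texture_sigma: tuple[float, float] = (2.0, 0.5)
    #: "centred": lesion near the volume centre (emulating lesion-centred
    #: crops, the classification regime); "free": anywhere in the gland
    #: interior (the reconstruction benchmark, which should exercise the
    #: codebook across spatial layouts)
    lesion_placement: str = "centred"

    def __post_init__(self):
        if self.class_label not in ("low", "medium", "high"):
            raise ValueError(f"unknown class '{self.class_label}'")
        if self.domain not in _DOMAIN_STYLE:
            raise ValueError(f"unknown domain '{self.domain}'")
        adc = self.class_means("adc")
        if not (adc["high"] < adc["medium"] < adc["low"]):
            raise ValueError("ADC lesion means must be ordered high < medium < low")

    def class_means(self, modality: str) -> dict[str, float]:
        base = self.contrast[modality]
        mid = base["medium"]
        return {c: mid + self.contrast_gap * (v - mid) for c, v in base.items()}


@dataclass
class Case:
    case_id: str
    t2: Volume3D
    adc: Volume3D
    label: str
    lesion_centre: tuple[int, int, int]
    lesion_mask: np.ndarray
    domain: str
    seed: int


def _ellipsoid_mask(shape, centre, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return acc <= 1.0


def _smooth_noise(rng, shape, sigma_inplane=3.0, sigma_z=0.8) -> np.ndarray:
    field_ = rng.normal(size=shape)
    return ndimage.gaussian_filter(field_, (sigma_inplane, sigma_inplane, sigma_z))


def generate_case(spec: PhantomSpec) -> Case:
    """One paired phantom; fully reproducible from the spec's seed.

    The geometry and base intensities depend only on the seed; the domain
    transform (contrast/noise/blur) is applied last with its own child
    stream, so the A and B renderings of the same seed share lesion
    geometry exactly.
    """
    geom_seed, dom_seed = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(geom_seed)
    X, Y, Z = spec.shape
    centre_g = (X / 2, Y / 2, Z / 2)
    gland = _ellipsoid_mask(spec.shape, centre_g, (0.42 * X, 0.42 * Y, 0.48 * Z))
    lesion_r = (
        max(2.0, 0.10 * X) * rng.uniform(0.8, 1.2),
        max(2.0, 0.10 * Y) * rng.uniform(0.8, 1.2),
        max(1.0, 0.22 * Z) * rng.uniform(0.8, 1.2),
    )
    if spec.lesion_placement == "centred":
        # lesion-centred patches (the clinical pipeline crops about the
        # lesion): small residual offset only
        bounds = ((0.42, 0.58), (0.42, 0.58), (0.4, 0.6))
    elif spec.lesion_placement == "free":
        bounds = ((0.3, 0.7), (0.3, 0.7), (0.35, 0.65))
    else:
        raise ValueError(f"unknown lesion placement '{spec.lesion_placement}'")
    for attempt in range(64):
        cand = (
            rng.uniform(bounds[0][0] * X, bounds[0][1] * X),
            rng.uniform(bounds[1][0] * Y, bounds[1][1] * Y),
            rng.uniform(bounds[2][0] * Z, bounds[2][1] * Z),
        )
        lesion = _ellipsoid_mask(spec.shape, cand, lesion_r)
        if lesion.any() and (lesion & ~gland).sum() == 0:
            break
    else:
        raise RuntimeError("could not place a lesion inside the gland")
    centre = tuple(int(round(c)) for c in cand)

    volumes = {}
    for modality in ("t2", "adc"):
        base = 0.15 + 0.35 * gland.astype(float)
        base = base + spec.texture_amplitude * _smooth_noise(
            rng, spec.shape, *spec.texture_sigma
        )
        mean = spec.class_means(modality)[spec.class_label]
        lesion_val = mean + rng.normal(0.0, spec.lesion_jitter)
        body = np.where(lesion, lesion_val, base)
        # soften the lesion boundary so reconstruction is non-trivial
        body = ndimage.gaussian_filter(body, (0.7, 0.7, 0.2))
        volumes[modality] = body

    style = _DOMAIN_STYLE[spec.domain]
    drng = np.random.default_rng(dom_seed)
    out = {}
    for modality, body in volumes.items():
        v = style["contrast"] * body
        if style["blur"] > 0:
            v = ndimage.gaussian_filter(v, (style["blur"], style["blur"], 0.0))
        sigma = style["noise"] * spec.noise_scale
        if sigma > 0:
            v = v + drng.normal(0.0, sigma, size=v.shape)
        out[modality] = np.clip(v, 0.0, 1.0)

    return Case(
        case_id=f"case-{spec.seed:08d}",
        t2=Volume3D(out["t2"], spacing=(0.5, 0.5, 1.5), lesion_centre=centre),
        adc=Volume3D(out["adc"], spacing=(0.5, 0.5, 1.5), lesion_centre=centre),
        label=spec.class_label,
        lesion_centre=centre,
        lesion_mask=lesion,
        domain=spec.domain,
        seed=spec.seed,
    )


def generate_dataset(
    n_per_class: int,
    domain: str = "A",
    seed: int = 0,
    shape: tuple[int, int, int] = (128, 128, 8),
    contrast_gap: float = 1.0,
) -> tuple[list[Case], pd.DataFrame]:
    """Balanced dataset (n_per_class per risk group) plus a manifest frame.

    Per-case seeds are spawned from the master seed, so different master
    seeds share no per-case streams, while the same master seed re-renders
    identical geometry in either domain.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    classes = ("low", "medium", "high")
    child_seeds = np.random.SeedSequence(seed).generate_state(3 * n_per_class)
    cases: list[Case] = []
    for i, label in enumerate(
        [c for c in classes for _ in range(n_per_class)]
    ):
        case_seed = int(child_seeds[i] % 2**31)
        spec = PhantomSpec(shape=shape, class_label=label, domain=domain,
                           seed=case_seed, contrast_gap=contrast_gap)
        case = generate_case(spec)
        case.case_id = f"{domain}-{label}-{i % n_per_class:03d}-{case_seed:08d}"
        cases.append(case)
    manifest = pd.DataFrame({
        "case_id": [c.case_id for c in cases],
        "label": [c.label for c in cases],
        "x": [c.lesion_centre[0] for c in cases],
        "y": [c.lesion_centre[1] for c in cases],
        "z": [c.lesion_centre[2] for c in cases],
        "domain": [c.domain for c in cases],
        "seed": [c.seed for c in cases],
    })
    return cases, manifest


def smooth_phantom_volumes(
    n: int,
    shape: tuple[int, int, int] = (32, 32, 4),
    seed: int = 0,
    modality: str = "t2",
) -> list[Volume3D]:
    """Noise-free "smooth" phantoms for reconstruction benchmarking.

    Same gland/lesion geometry and class balance as the classification
    datasets, but with the additive acquisition noise switched off —
    smooth piecewise structure only, the regime in which a codebook
    autoencoder's capacity (not its denoising behaviour) is measured.
    """
    classes = ("low", "medium", "high")
    child = np.random.SeedSequence(seed).generate_state(n)
    out = []
    for i in range(n):
        spec = PhantomSpec(shape=shape, class_label=classes[i % 3],
                           seed=int(child[i] % 2**31), noise_scale=0.0,
                           lesion_placement="free")
        case = generate_case(spec)
        out.append(getattr(case, modality))
    return out


def write_dataset(cases: list[Case], manifest: pd.DataFrame,
                  outdir: str | Path) -> None:
    """NIfTI pairs plus the sidecar manifest CSV (preprocess-compatible)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        save_nifti(case.t2, outdir / f"{case.case_id}_t2.nii")
        save_nifti(case.adc, outdir / f"{case.case_id}_adc.nii")
    manifest.to_csv(outdir / "manifest.csv", index=False)


def read_dataset(indir: str | Path) -> list[Case]:
    """Load NIfTI pairs + manifest written by :func:`write_dataset`.

    Lesion masks are not stored on disk; loaded cases carry ``None``.
    """
    from .volume import load_nifti

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    cases = []
    for row in manifest.itertuples():
        centre = (int(row.x), int(row.y), int(row.z))
        t2 = load_nifti(indir / f"{row.case_id}_t2.nii")
        adc = load_nifti(indir / f"{row.case_id}_adc.nii")
        t2.lesion_centre = adc.lesion_centre = centre
        cases.append(Case(
            case_id=row.case_id, t2=t2, adc=adc, label=row.label,
            lesion_centre=centre, lesion_mask=None,
            domain=getattr(row, "domain", "A"), seed=int(getattr(row, "seed", 0)),
        ))
    return cases


def oracle_accuracy(cases: list[Case]) -> float:
    """Accuracy of thresholding mean ADC intensity inside the lesion mask.

    The thresholds are the midpoints of the generator's own class means —
    a Bayes-style reference for how separable the phantoms are by
    construction.
    """
    means = DEFAULT_CONTRAST["adc"]
    hi_cut = (means["high"] + means["medium"]) / 2
    lo_cut = (means["medium"] + means["low"]) / 2
    correct = 0
    for case in cases:
        m = float(case.adc.data[case.lesion_mask].mean())
        pred = "high" if m < hi_cut else ("medium" if m < lo_cut else "low")
        correct += pred == case.label
    return correct / len(cases)
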