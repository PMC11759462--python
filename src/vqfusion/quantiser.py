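"""Vector quantisation: codebook, nearest-code assignment, straight-through
gradients and the three-term VQ objective.

The discrete latent space is a codebook ``D ∈ R^{K×d}``. An encoder output
grid ``e`` of shape ``(c, x, y, z)`` is viewed as ``m = x·y·z`` fibres of
width ``c``; each fibre is replaced by its nearest codebook row under
Euclidean distance (ties to the lowest index). Training uses the classic
three-term objective

    L = MSE(recon, target) + Σ_i ||sg(e_i) − l_k||₂ + β Σ_i ||e_i − sg(l_k)||₂

where ``sg`` is the stop-gradient: the middle term moves codebook rows
toward the (frozen) encoder fibres, the commitment term keeps encoder
fibres near their assigned (frozen) codes. The quantisation step itself
passes gradients straight through, i.e. the decoder-input gradient is
copied to the encoder output unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Tensor, Parameter

__all__ = [
    "Codebook", "LatentGrid", "QuantisedGrid", "VqLossTerms",
    "init_codebook", "nearest_code", "quantise", "straight_through",
    "vq_losses", "vq_loss_tensor", "codebook_usage",
    "save_codebook", "load_codebook",
]

_NORM_EPS = 1e-12  # guards the l2-norm gradient at exactly zero


@dataclass
class Codebook:
    """K learned code vectors of width d (the dictionary)."""

    codes: np.ndarray  # (K, d)
    seed: int | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.float64)
        if self.codes.ndim != 2:
            raise ValueError("codebook must be a K×d matrix")
        if not np.all(np.isfinite(self.codes)):
            raise ValueError("codebook entries must be finite")

    @property
    def K(self) -> int:
        return self.codes.shape[0]

    @property
    def d(self) -> int:
        return self.codes.shape[1]


@dataclass
class LatentGrid:
    """Continuous encoder output: (c, x, y, z); fibres are the c-vectors."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("latent grid must be (c, x, y, z)")

    @property
    def c(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return int(np.prod(self.values.shape[1:]))


@dataclass
class QuantisedGrid:
    """Codebook-snapped latent grid plus the per-site code indices."""

    values: np.ndarray   # (c, x, y, z)
    indices: np.ndarray  # (x, y, z) ints

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.values.shape[1:] != self.indices.shape:
            raise ValueError("values and indices disagree on spatial shape")


@dataclass
class VqLossTerms:
    reconstruction: float
    codebook_term: float
    commitment_term: float
    beta: float

    @property
    def total(self) -> float:
        return self.reconstruction + self.codebook_term + self.beta * self.commitment_term


def init_codebook(K: int, d: int, seed: int) -> Codebook:
    """Uniform initialisation on [−1/K, 1/K], reproducible by seed."""
    if K < 1 or d < 1:
        raise ValueError(f"K and d must be positive, got K={K}, d={d}")
    rng = np.random.default_rng(seed)
    return Codebook(rng.uniform(-1.0 / K, 1.0 / K, size=(K, d)), seed=seed)


def nearest_code(vector: np.ndarray, codebook: Codebook) -> int:
    """Index of the Euclidean-nearest codebook row; ties to the lowest index."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != (codebook.d,):
        raise ValueError(
            f"vector has shape {vector.shape}, codebook expects ({codebook.d},)"
        )
    d2 = np.sum((codebook.codes - vector) ** 2, axis=1)
    return int(np.argmin(d2))  # argmin returns the first (lowest) minimiser


def _assign(flat: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Vectorised nearest-row assignment for (m, d) fibres.

    Squared distances are formed directly as Σ(e−l)², not via the expanded
    ‖e‖²−2e·l+‖l‖² identity, so exact ties resolve identically to a
    per-pair brute-force computation. Chunked over sites to bound memory.
    """
    m = flat.shape[0]
    out = np.empty(m, dtype=np.int64)
    chunk = max(1, int(2**22 // max(1, codes.size)))
    for lo in range(0, m, chunk):
        hi = min(m, lo + chunk)
        d2 = np.sum((flat[lo:hi, None, :] - codes[None, :, :]) ** 2, axis=2)
        out[lo:hi] = np.argmin(d2, axis=1)
    return out


def quantise(latent: LatentGrid, codebook: Codebook) -> QuantisedGrid:
    """Snap every fibre of the latent grid to its nearest codebook row."""
    if latent.c != codebook.d:
        raise ValueError(
            f"latent channel count {latent.c} != codebook dimensionality {codebook.d}"
        )
    c, x, y, z = latent.values.shape
    flat = latent.values.reshape(c, -1).T  # (m, d)
    idx = _assign(flat, codebook.codes)
    values = codebook.codes[idx].T.reshape(c, x, y, z)
    return QuantisedGrid(values=values, indices=idx.reshape(x, y, z))


def straight_through(latent: Tensor, quantised_values: np.ndarray) -> Tensor:
    """Forward the quantised values exactly; backward the identity to the
    latent (the quantisation jump contributes no gradient)."""
    quantised_values = np.asarray(quantised_values)
    if latent.shape != quantised_values.shape:
        raise ValueError(
            f"latent shape {latent.shape} != quantised shape {quantised_values.shape}"
        )

    def bw(g, grads):
        Tensor._send(grads, latent, g)

    return Tensor(quantised_values.astype(latent.data.dtype, copy=True),
                  _parents=(latent,), _backward=bw)


def _sum_site_norms(diff: Tensor) -> Tensor:
    """Σ over sites of the l2 norm of each channel fibre; diff is (c,x,y,z)."""
    sq = (diff**2).sum(axis=0)  # (x,y,z) squared norms
    return ((sq + _NORM_EPS) ** 0.5).sum()


def vq_loss_tensor(
    reconstruction: Tensor,
    target: np.ndarray,
    latent: Tensor,
    codebook_param: Parameter,
    indices: np.ndarray,
    beta: float = 0.25,
) -> tuple[Tensor, VqLossTerms]:
    """Differentiable three-term objective for training.

    Gradients: the reconstruction term reaches the decoder and (through the
    straight-through path) the encoder; the codebook term reaches only the
    codebook rows; the commitment term only the encoder.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    target = np.asarray(target, dtype=np.float64)
    if reconstruction.shape != target.shape:
        raise ValueError("reconstruction and target shapes differ")
    flat_idx = np.asarray(indices, dtype=np.int64).ravel()
    rec = ((reconstruction - Tensor(target)) ** 2).mean()
    c = latent.shape[0]
    lat_fibres = latent.reshape(c, -1).transpose(1, 0)  # (m, c)
    code_rows = codebook_param[flat_idx]                # (m, c), grads scatter-add
    cb_term = _sum_site_norms((code_rows - Tensor(lat_fibres.data)).transpose(1, 0))
    commit = _sum_site_norms((lat_fibres - Tensor(code_rows.data)).transpose(1, 0))
    total = rec + cb_term + beta * commit
    terms = VqLossTerms(
        reconstruction=float(rec.data),
        codebook_term=float(cb_term.data),
        commitment_term=float(commit.data),
        beta=float(beta),
    )
    return total, terms


def vq_losses(
    reconstruction: np.ndarray,
    target: np.ndarray,
    latent: LatentGrid,
    quantised: QuantisedGrid,
    beta: float = 0.25,
) -> VqLossTerms:
    """Evaluate the three loss terms (no gradients)."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if reconstruction.shape != target.shape:
        raise ValueError("reconstruction and target shapes differ")
    if latent.values.shape != quantised.values.shape:
        raise ValueError("latent and quantised shapes differ")
    rec = float(np.mean((reconstruction - target) ** 2))
    diff = latent.values - quantised.values  # (c,x,y,z)
    site_norms = np.sqrt(np.sum(diff**2, axis=0))
    term = float(site_norms.sum())
    # codebook and commitment terms share the same value; they differ only in
    # which side the stop-gradient freezes
    return VqLossTerms(rec, term, term, float(beta))


def codebook_usage(indices: np.ndarray, K: int) -> np.ndarray:
    """Histogram of code usage (diagnostics only; no dead-code reseeding)."""
    return np.bincount(np.asarray(indices).ravel(), minlength=K)


def save_codebook(codebook: Codebook, path: str | Path) -> None:
    """Serialise K, d, seed and the code matrix to a plain-text npz-free file."""
    path = Path(path)
    header = f"# codebook K={codebook.K} d={codebook.d} seed={codebook.seed}"
    np.savetxt(path, codebook.codes, header=header, comments="")


def load_codebook(path: str | Path) -> Codebook:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    meta = dict(tok.split("=") for tok in header.replace("# codebook ", "").split())
    codes = np.loadtxt(path, skiprows=1, ndmin=2)
    seed = None if meta.get("seed") == "None" else int(meta["seed"])
    cb = Codebook(codes, seed=seed)
    if cb.K != int(meta["K"]) or cb.d != int(meta["d"]):
        raise ValueError("codebook file header disagrees with matrix shape")
    return cb
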