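"""Neural-network building blocks on top of the autodiff engine.

Conventions: volumetric feature maps are channel-last ``(N, X, Y, Z, C)``
(so latent fibres and token rasters are contiguous); token sequences are
``(N, T, D)``. Convolutions are stride-1 with "same" zero-padding; spatial
downsampling is by in-plane max-pooling and upsampling by in-plane
bilinear interpolation, which keeps the slice axis (Z) untouched — the
anisotropy contract for thick-slice MR.

Conv3d, GroupNorm, pooling and upsampling carry hand-derived backward
passes (they dominate the runtime); everything else composes autodiff
primitives.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "Linear", "Conv3d", "GroupNorm", "LayerNorm",
    "max_pool_inplane", "upsample_bilinear_inplane",
    "kaiming_normal", "trunc_normal",
]


# ----------------------------------------------------------------- initialisers
def kaiming_normal(rng: np.random.Generator, shape, fan_in: int, a: float = 0.01):
    """He initialisation for leaky-ReLU networks (fan-in mode)."""
    gain = np.sqrt(2.0 / (1.0 + a**2))
    std = gain / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02, bound: float = 2.0):
    """Normal(0, std) resampled until within ±bound·std (rejection sampling)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > bound * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > bound * std
    return out


class Parameter(Tensor):
    """A trainable tensor. ``decay=False`` marks parameters that decoupled
    weight decay must skip (biases, normalisation gains, class tokens,
    positional embeddings — the standard transformer recipe)."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


class Module:
    """Minimal container: tracks parameters and submodules by attribute."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[prefix + k] = v.data.copy()
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{prefix}{k}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{prefix}{k}.{i}"] = item.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                v.data = np.asarray(state[prefix + k]).copy()
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{k}.{i}.")
                    elif isinstance(item, Parameter):
                        item.data = np.asarray(state[f"{prefix}{k}.{i}"]).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype) -> "Module":
        """Cast all parameters in place (e.g. float32 for training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    @property
    def dtype(self):
        params = self.parameters()
        return params[0].data.dtype if params else np.float64

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init: str = "kaiming", bias: bool = True):
        if init == "kaiming":
            w = kaiming_normal(rng, (in_features, out_features), fan_in=in_features)
        elif init == "trunc_normal":
            # variance-preserving truncated normal (±2σ, σ = 1/√fan_in)
            w = trunc_normal(rng, (in_features, out_features),
                             std=1.0 / np.sqrt(in_features))
        else:
            raise ValueError(f"unknown init '{init}'")
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    """Stride-1 "same" 3-D convolution on channel-last (N,X,Y,Z,C) maps.

    Kernel (3,3,1) is a purely in-plane (2-D) convolution; (3,3,3) mixes
    adjacent slices. Borders are replicate-padded so spatially constant
    inputs map to constant outputs (no zero-padding ring — important for
    intensity fidelity at patch borders). Implemented as a sum of
    per-offset matmuls on shifted views, which keeps every BLAS operand
    contiguous.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel, rng,
                 init: str = "kaiming"):
        self.kernel = tuple(kernel)
        kx, ky, kz = self.kernel
        fan_in = in_channels * kx * ky * kz
        shape = (kx, ky, kz, in_channels, out_channels)
        if init == "kaiming":
            w = kaiming_normal(rng, shape, fan_in=fan_in)
        elif init == "trunc_normal":
            w = trunc_normal(rng, shape, std=1.0 / np.sqrt(fan_in))
        else:
            raise ValueError(f"unknown init '{init}'")
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 5:
            raise ValueError(f"Conv3d expects (N,X,Y,Z,C), got shape {x.shape}")
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"Conv3d expects {self.in_channels} input channels, got {x.shape[-1]}"
            )
        kx, ky, kz = self.kernel
        px, py, pz = kx // 2, ky // 2, kz // 2
        N, X, Y, Z, C = x.shape
        w, b = self.weight, self.bias
        xp = np.pad(x.data, ((0, 0), (px, px), (py, py), (pz, pz), (0, 0)),
                    mode="edge")
        out = np.broadcast_to(
            b.data.astype(x.data.dtype), (N, X, Y, Z, self.out_channels)
        ).copy()
        for i in range(kx):
            for j in range(ky):
                for k in range(kz):
                    out += xp[:, i:i + X, j:j + Y, k:k + Z, :] @ w.data[i, j, k]
        conv = self

        def bw(g, grads):
            if b.requires_grad:
                Tensor._send(grads, b, g.sum(axis=(0, 1, 2, 3)))
            if w.requires_grad:
                gw = np.empty_like(w.data)
                gflat = g.reshape(-1, conv.out_channels)
                for i in range(kx):
                    for j in range(ky):
                        for k in range(kz):
                            seg = xp[:, i:i + X, j:j + Y, k:k + Z, :]
                            gw[i, j, k] = seg.reshape(-1, C).T @ gflat
                Tensor._send(grads, w, gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kx):
                    for j in range(ky):
                        for k in range(kz):
                            gxp[:, i:i + X, j:j + Y, k:k + Z, :] += g @ w.data[i, j, k].T
                # fold replicate-pad gradients back onto the border voxels
                for axis, p in ((1, px), (2, py), (3, pz)):
                    if p == 0:
                        continue
                    lead = [slice(None)] * 5
                    lead[axis] = slice(0, p)
                    first = [slice(None)] * 5
                    first[axis] = slice(p, p + 1)
                    gxp[tuple(first)] += gxp[tuple(lead)].sum(
                        axis=axis, keepdims=True
                    )
                    trail = [slice(None)] * 5
                    trail[axis] = slice(gxp.shape[axis] - p, gxp.shape[axis])
                    last = [slice(None)] * 5
                    last[axis] = slice(gxp.shape[axis] - p - 1,
                                       gxp.shape[axis] - p)
                    gxp[tuple(last)] += gxp[tuple(trail)].sum(
                        axis=axis, keepdims=True
                    )
                Tensor._send(
                    grads, x, gxp[:, px:px + X, py:py + Y, pz:pz + Z, :]
                )

        return Tensor(out, _parents=(x, w, b), _backward=bw)


class GroupNorm(Module):
    """Group normalisation over channel groups of a channel-last map.

    Fused forward/backward (the standard normalisation gradient), since
    this runs at full spatial resolution in every block.
    """

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups != 0:
            raise ValueError(f"groups={groups} must divide channels={channels}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        C, g = self.channels, self.groups
        if x.shape[-1] != C:
            raise ValueError(f"expected {C} channels, got {x.shape[-1]}")
        shape = x.shape
        N = shape[0]
        xr = x.data.reshape(N, -1, g, C // g)  # (N, S, g, Cg)
        mu = xr.mean(axis=(1, 3), keepdims=True)
        xc = xr - mu
        var = (xc**2).mean(axis=(1, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xh = xc * inv
        gamma, beta = self.weight, self.bias
        gam = gamma.data.astype(x.data.dtype).reshape(g, C // g)
        bet = beta.data.astype(x.data.dtype).reshape(g, C // g)
        out = (xh * gam + bet).reshape(shape)

        def bw(grad, grads):
            gr = grad.reshape(N, -1, g, C // g)
            if gamma.requires_grad:
                Tensor._send(grads, gamma, (gr * xh).sum(axis=(0, 1)).ravel())
            if beta.requires_grad:
                Tensor._send(grads, beta, gr.sum(axis=(0, 1)).ravel())
            if x.requires_grad:
                dxh = gr * gam
                m1 = dxh.mean(axis=(1, 3), keepdims=True)
                m2 = (dxh * xh).mean(axis=(1, 3), keepdims=True)
                gx = inv * (dxh - m1 - xh * m2)
                Tensor._send(grads, x, gx.reshape(shape))

        return Tensor(out, _parents=(x, gamma, beta), _backward=bw)


class LayerNorm(Module):
    """Layer normalisation over the last axis (token width)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.weight + self.bias


def max_pool_inplane(x: Tensor) -> Tensor:
    """2×2 in-plane max pooling on (N,X,Y,Z,C); slice axis preserved."""
    N, X, Y, Z, C = x.shape
    if X % 2 or Y % 2:
        raise ValueError(f"in-plane extent ({X},{Y}) must be even for 2x2 pooling")
    win = x.data.reshape(N, X // 2, 2, Y // 2, 2, Z, C)
    flat = win.transpose(0, 1, 3, 5, 6, 2, 4).reshape(N, X // 2, Y // 2, Z, C, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g, grads):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(N, X // 2, Y // 2, Z, C, 2, 2)
        gx = gx.transpose(0, 1, 5, 2, 6, 3, 4).reshape(N, X, Y, Z, C)
        Tensor._send(grads, x, gx)

    return Tensor(out, _parents=(x,), _backward=bw)


def _upsample_matrix(n: int) -> np.ndarray:
    """2x bilinear interpolation matrix (2n × n), edge-clamped."""
    U = np.zeros((2 * n, n))
    for i in range(2 * n):
        # output sample i sits at input coordinate (i + 0.5)/2 - 0.5
        pos = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(pos))
        frac = pos - lo
        lo_c, hi_c = np.clip(lo, 0, n - 1), np.clip(lo + 1, 0, n - 1)
        U[i, lo_c] += 1.0 - frac
        U[i, hi_c] += frac
    return U


def upsample_bilinear_inplane(x: Tensor) -> Tensor:
    """2× in-plane bilinear upsampling on (N,X,Y,Z,C); slice axis untouched."""
    N, X, Y, Z, C = x.shape
    Ux = _upsample_matrix(X).astype(x.data.dtype)
    Uy = _upsample_matrix(Y).astype(x.data.dtype)
    out = np.einsum("ax,nxyzc->nayzc", Ux, x.data, optimize=True)
    out = np.einsum("by,nayzc->nabzc", Uy, out, optimize=True)

    def bw(g, grads):
        gx = np.einsum("by,nabzc->nayzc", Uy, g, optimize=True)
        gx = np.einsum("ax,nayzc->nxyzc", Ux, gx, optimize=True)
        Tensor._send(grads, x, gx)

    return Tensor(out, _parents=(x,), _backward=bw)
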