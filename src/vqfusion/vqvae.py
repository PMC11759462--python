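"""Hybrid 2D/3D vector-quantised auto-encoder and stage-1 training.

Thick-slice prostate MR is anisotropic (in-plane spacing ≪ slice spacing),
so the encoder downsamples only in-plane: a stack of 2-D pre-activation
residual blocks (3×3×1 kernels) each followed by 2×2 in-plane max-pooling,
capped by one non-downsampling 3-D block (3×3×3) that mixes adjacent
slices and widens the features to the codebook dimensionality. The decoder
mirrors this with bilinear in-plane upsampling. The slice count Z is
preserved end to end.

One independent VQ-VAE (encoder, decoder, codebook) is trained per
modality; the T2 and ADC dictionaries never share parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam, Conv3d, GroupNorm, Module, Parameter, Tensor,
    max_pool_inplane, upsample_bilinear_inplane,
)
from .quantiser import (
    Codebook, LatentGrid, QuantisedGrid, _assign, init_codebook, quantise,
    straight_through, _NORM_EPS,
)
from .volume import Volume3D

__all__ = [
    "VqVaeConfig", "MINI_CONFIG", "FULL_CONFIG", "VqVaeEncoder",
    "VqVaeDecoder", "PreActBlock", "encode", "decode", "train_stage1",
    "Stage1Model", "TrainingDivergedError", "save_stage1", "load_stage1",
    "encode_batch", "reconstruction_mse",
]


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class VqVaeConfig:
    """Architecture and stage-1 training hyper-parameters."""

    n_2d_blocks: int = 3
    channels: tuple[int, ...] = (32, 64, 128)
    latent_channels: int = 256        # equals codebook d and the token width
    groups: int = 2                   # group-normalisation groups
    negative_slope: float = 0.01      # leaky-ReLU slope
    K: int = 128                      # codebook size
    beta: float = 0.25                # commitment weight
    lr: float = 5e-4
    weight_decay: float = 0.01
    epochs: int = 200
    batch_size: int = 4
    dtype: str = "float32"   # training precision; the public API is float64
    #: stop early once the epoch reconstruction MSE has not improved by
    #: >1% over this many epochs (None = run the full budget)
    plateau_patience: int | None = None
    #: every this many steps, codes that received no assignments since the
    #: last check are re-seeded at random encoder fibres (0 disables).
    #: Without it, low-diversity data collapses onto one or two codes and
    #: distinct intensities become inseparable.
    reseed_every: int = 50

    def __post_init__(self):
        if len(self.channels) != self.n_2d_blocks:
            raise ValueError("channels must list one width per 2-D block")
        for c in self.channels + (self.latent_channels,):
            if c % self.groups and c > self.groups:
                raise ValueError(f"groups={self.groups} must divide width {c}")


#: Full-scale profile: 128×128×8 patches → 256-wide latent at 16×16×8.
FULL_CONFIG = VqVaeConfig()

#: Desk-scale profile: 32×32×4 phantoms → 32-wide latent at 8×8×4;
#: a higher learning rate and short schedule suit the few-hundred-step budget.
MINI_CONFIG = VqVaeConfig(
    n_2d_blocks=2, channels=(8, 16), latent_channels=32,
    lr=2e-3, epochs=100, batch_size=8,
)


def _norm(groups: int, channels: int) -> GroupNorm:
    # a 1-channel input cannot be split into 2 groups; fall back to 1
    g = groups if channels % groups == 0 else 1
    return GroupNorm(g, channels)


class PreActBlock(Module):
    """Pre-activation residual block: (GN → LeakyReLU → conv) × 2 + shortcut.

    The residual branch starts at zero (second conv zero-initialised) so
    every block is the identity at initialisation, and projection
    shortcuts use variance-preserving (gain-1) init — deep stacks of
    blocks then neither amplify nor attenuate the signal before training,
    which substantially speeds up short desk-scale fits.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel, groups: int,
                 negative_slope: float, rng: np.random.Generator,
                 init: str = "kaiming"):
        self.norm1 = _norm(groups, in_ch)
        self.conv1 = Conv3d(in_ch, out_ch, kernel, rng, init=init)
        self.norm2 = _norm(groups, out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, kernel, rng, init=init)
        self.conv2.weight.data[:] = 0.0
        if in_ch != out_ch:
            self.shortcut = Conv3d(in_ch, out_ch, (1, 1, 1), rng, init=init)
            self.shortcut.weight.data = rng.normal(
                0.0, 1.0 / np.sqrt(in_ch), self.shortcut.weight.data.shape
            )
        else:
            self.shortcut = None
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).leaky_relu(self.negative_slope))
        h = self.conv2(self.norm2(h).leaky_relu(self.negative_slope))
        s = self.shortcut(x) if self.shortcut is not None else x
        return h + s


class VqVaeEncoder(Module):
    """2-D downsampling blocks + one 3-D block to the latent width."""

    def __init__(self, config: VqVaeConfig, rng: np.random.Generator):
        self.config = config
        blocks = []
        in_ch = 1
        for ch in config.channels:
            blocks.append(PreActBlock(in_ch, ch, (3, 3, 1), config.groups,
                                      config.negative_slope, rng))
            in_ch = ch
        self.blocks = blocks
        # "pre-quantisation block": widens to the codebook dimensionality,
        # mixing adjacent slices with a 3-D kernel; frozen in stage 2
        self.pre_quant = PreActBlock(in_ch, config.latent_channels, (3, 3, 3),
                                     config.groups, config.negative_slope, rng)

    def forward(self, x: Tensor) -> Tensor:
        n = self.config.n_2d_blocks
        for axis, extent in zip("XY", x.shape[1:3]):
            if extent % (2**n):
                raise ValueError(
                    f"axis {axis} extent {extent} not divisible by 2^{n}"
                )
        for block in self.blocks:
            x = max_pool_inplane(block(x))
        return self.pre_quant(x)


class VqVaeDecoder(Module):
    """Mirror of the encoder: 3-D block, then bilinear-upsampled 2-D blocks."""

    def __init__(self, config: VqVaeConfig, rng: np.random.Generator):
        self.config = config
        chs = list(config.channels)
        self.post_quant = PreActBlock(config.latent_channels, chs[-1], (3, 3, 3),
                                      config.groups, config.negative_slope, rng)
        blocks = []
        widths = chs[::-1]  # e.g. (128, 64, 32)
        for i, ch in enumerate(widths):
            nxt = widths[i + 1] if i + 1 < len(widths) else widths[-1]
            blocks.append(PreActBlock(ch, nxt, (3, 3, 1), config.groups,
                                      config.negative_slope, rng))
        self.blocks = blocks
        self.out_conv = Conv3d(widths[-1], 1, (3, 3, 1), rng)

    def forward(self, z: Tensor) -> Tensor:
        x = self.post_quant(z)
        for block in self.blocks:
            x = block(upsample_bilinear_inplane(x))
        return self.out_conv(x)


# ------------------------------------------------------------------ public API
def encode(volume: Volume3D, encoder: VqVaeEncoder) -> LatentGrid:
    """Map one volume to its continuous latent grid (c, X/2^n, Y/2^n, Z)."""
    out = encode_batch(volume.data[None], encoder)
    return LatentGrid(out[0].transpose(3, 0, 1, 2))


def encode_batch(data: np.ndarray, encoder: VqVaeEncoder) -> np.ndarray:
    """Encode a (N,X,Y,Z) stack; returns channel-last latents (N,x,y,z,c)."""
    x = Tensor(np.ascontiguousarray(data[..., None]).astype(encoder.dtype))
    return encoder(x).data


def decode(grid_values: np.ndarray, decoder: VqVaeDecoder) -> Volume3D:
    """Map a (quantised) latent grid back to image space."""
    grid_values = np.asarray(grid_values, dtype=np.float64)
    if grid_values.shape[0] != decoder.config.latent_channels:
        raise ValueError(
            f"grid has {grid_values.shape[0]} channels, decoder expects "
            f"{decoder.config.latent_channels}"
        )
    cl = grid_values.transpose(1, 2, 3, 0)[None]  # channel-last
    out = decoder(Tensor(np.ascontiguousarray(cl).astype(decoder.dtype)))
    return Volume3D(out.data[0, ..., 0])


@dataclass
class Stage1Model:
    """Frozen product of stage 1 for one modality."""

    encoder: VqVaeEncoder
    decoder: VqVaeDecoder
    codebook: Codebook
    loss_history: list[dict] = field(default_factory=list)

    def reconstruct(self, volume: Volume3D) -> Volume3D:
        latent = encode(volume, self.encoder)
        q = quantise(latent, self.codebook)
        return decode(q.values, self.decoder)


def _batch_vq_forward(encoder, decoder, codebook_param, batch, beta):
    """One differentiable stage-1 forward pass over a (N,X,Y,Z) batch."""
    target = np.ascontiguousarray(batch[..., None])  # (N,X,Y,Z,1)
    x = Tensor(target)
    latent = encoder(x)          # (N,x,y,z,C) channel-last
    N, C = latent.shape[0], latent.shape[-1]
    flat = latent.data.reshape(-1, C)  # contiguous fibre view
    idx = _assign(flat, codebook_param.data)
    quant_flat = codebook_param.data[idx]
    quant = quant_flat.reshape(latent.shape)
    z = straight_through(latent, quant)
    recon = decoder(z)
    rec_loss = ((recon - Tensor(target)) ** 2).mean()
    # Codebook / commitment terms in the squared-distance form of the
    # cited vector-quantisation objective, as per-site means. The
    # unsquared site norms reported by the quantiser module have
    # distance-independent gradient magnitude, which at desk scale locks
    # every latent onto the first code that wins an assignment (code
    # collapse); the squared form's gradient vanishes near the assigned
    # code and trains stably with the same beta.
    lat_fibres = latent.reshape(-1, C)
    code_rows = codebook_param[idx]
    cb = ((code_rows - Tensor(flat)) ** 2).sum(axis=1).mean()
    commit = ((lat_fibres - Tensor(quant_flat)) ** 2).sum(axis=1).mean()
    total = rec_loss + cb + beta * commit
    return total, float(rec_loss.data), idx


def _plateaued(epoch_mses: list[float], patience: int, rel: float = 0.01) -> bool:
    """True once the running best MSE stopped improving by >rel for patience epochs."""
    if len(epoch_mses) <= patience:
        return False
    best_before = min(epoch_mses[:-patience])
    best_recent = min(epoch_mses[-patience:])
    return best_recent > best_before * (1.0 - rel)


def train_stage1(
    datasets: dict[str, list[Volume3D]],
    config: VqVaeConfig,
    seed: int,
    max_steps: int | None = None,
) -> dict[str, Stage1Model]:
    """Train one independent VQ-VAE per modality.

    ``datasets`` maps modality name (e.g. ``"t2"``, ``"adc"``) to its
    training volumes (already preprocessed to [0, 1]). Returns one
    :class:`Stage1Model` per modality; the two modalities share nothing,
    not even the random stream consumed during initialisation (each gets a
    modality-specific child seed).
    """
    if not datasets or any(len(v) == 0 for v in datasets.values()):
        raise ValueError("each modality needs a nonempty training set")
    out: dict[str, Stage1Model] = {}
    for mod_i, (name, volumes) in enumerate(sorted(datasets.items())):
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(len(datasets))[mod_i])
        dtype = np.dtype(config.dtype)
        encoder = VqVaeEncoder(config, rng).astype(dtype)
        decoder = VqVaeDecoder(config, rng).astype(dtype)
        codebook0 = init_codebook(config.K, config.latent_channels,
                                  seed=int(rng.integers(2**31)))
        codebook_param = Parameter(codebook0.codes.astype(dtype))
        params = encoder.parameters() + decoder.parameters() + [codebook_param]
        opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
        data = np.stack([v.data for v in volumes]).astype(dtype)
        n = len(volumes)
        history: list[dict] = []
        step = 0
        budget = max_steps if max_steps is not None else config.epochs * max(
            1, n // config.batch_size
        )
        usage = np.zeros(config.K, dtype=np.int64)
        for epoch in range(10**9):
            order = rng.permutation(n)
            epoch_rec, n_batches = 0.0, 0
            for lo in range(0, n, config.batch_size):
                if step >= budget:
                    break
                batch = data[order[lo:lo + config.batch_size]]
                total, rec, idx = _batch_vq_forward(
                    encoder, decoder, codebook_param, batch, config.beta
                )
                if not np.isfinite(total.data):
                    raise TrainingDivergedError(epoch)
                opt.zero_grad()
                total.backward()
                opt.step()
                usage += np.bincount(idx, minlength=config.K)
                step += 1
                if config.reseed_every and step % config.reseed_every == 0:
                    dead = usage == 0
                    if dead.any():
                        # restart dead codes at random encoder fibres so the
                        # dictionary keeps covering the occupied latent space
                        enc_out = encoder(Tensor(batch[..., None])).data
                        fibres = enc_out.reshape(-1, enc_out.shape[-1])
                        pick = rng.integers(0, len(fibres), size=int(dead.sum()))
                        codebook_param.data[dead] = fibres[pick]
                    usage[:] = 0
                epoch_rec += rec
                n_batches += 1
            if n_batches:
                history.append(
                    {"epoch": epoch, "step": step,
                     "reconstruction_mse": epoch_rec / n_batches}
                )
            if step >= budget:
                break
            if config.plateau_patience is not None and _plateaued(
                [h["reconstruction_mse"] for h in history],
                config.plateau_patience,
            ):
                break
        out[name] = Stage1Model(
            encoder, decoder,
            Codebook(codebook_param.data.copy(), seed=codebook0.seed),
            history,
        )
    return out


def reconstruction_mse(model: Stage1Model, volumes: list[Volume3D]) -> float:
    """Mean squared reconstruction error over a set of volumes."""
    errs = [
        float(np.mean((model.reconstruct(v).data - v.data) ** 2)) for v in volumes
    ]
    return float(np.mean(errs))


# -------------------------------------------------------------- checkpointing
def save_stage1(models: dict[str, Stage1Model], config: VqVaeConfig,
                path: str | Path) -> None:
    """Bundle per-modality weights, codebooks and the config into one .npz."""
    blobs: dict[str, np.ndarray] = {}
    for name, m in models.items():
        for k, v in m.encoder.state_dict().items():
            blobs[f"{name}/encoder/{k}"] = v
        for k, v in m.decoder.state_dict().items():
            blobs[f"{name}/decoder/{k}"] = v
        blobs[f"{name}/codebook"] = m.codebook.codes
    import json

    blobs["__config__"] = np.frombuffer(
        json.dumps({
            "n_2d_blocks": config.n_2d_blocks, "channels": list(config.channels),
            "latent_channels": config.latent_channels, "groups": config.groups,
            "negative_slope": config.negative_slope, "K": config.K,
            "beta": config.beta,
        }).encode(), dtype=np.uint8,
    )
    np.savez(path, **blobs)


def load_stage1(path: str | Path) -> tuple[dict[str, Stage1Model], VqVaeConfig]:
    import json

    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]).decode())
        config = VqVaeConfig(
            n_2d_blocks=cfg["n_2d_blocks"], channels=tuple(cfg["channels"]),
            latent_channels=cfg["latent_channels"], groups=cfg["groups"],
            negative_slope=cfg["negative_slope"], K=cfg["K"], beta=cfg["beta"],
        )
        names = sorted({k.split("/")[0] for k in z.files if "/" in k})
        rng = np.random.default_rng(0)  # shapes only; weights overwritten
        out = {}
        for name in names:
            enc, dec = VqVaeEncoder(config, rng), VqVaeDecoder(config, rng)
            enc.load_state_dict(
                {k.split("/", 2)[2]: z[k] for k in z.files
                 if k.startswith(f"{name}/encoder/")}
            )
            dec.load_state_dict(
                {k.split("/", 2)[2]: z[k] for k in z.files
                 if k.startswith(f"{name}/decoder/")}
            )
            out[name] = Stage1Model(enc, dec, Codebook(z[f"{name}/codebook"]))
    return out, config
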