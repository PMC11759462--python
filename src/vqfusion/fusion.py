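"""Dual-stream transformer with class-token cross-attention fusion (stage 2).

Each modality's quantised latent grid passes through three trainable
pre-activation residual conv blocks, is flattened into ``m = x·y·z`` tokens
(raster order, x fastest) with a learned class token prepended and learned
positional encodings added, and runs through its own transformer stream.
After every transformer layer the two streams exchange information: each
stream's class token forms a single multi-head attention query over the
*other* stream's patch tokens, and the attended value is added residually
back onto the class token. The final T2 and ADC class tokens are
concatenated and fed to an MLP head for 3-class risk prediction.

Stage-1 components (encoders, pre-quantisation blocks, codebooks) are
frozen: they are simply never handed to the optimiser, and training
asserts they are bit-identical afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AdamW, LayerNorm, Linear, Module, Parameter, Tensor, concatenate,
    cosine_warmup, trunc_normal,
)
from .quantiser import _assign, quantise
from .vqvae import (
    PreActBlock, Stage1Model, TrainingDivergedError, encode, encode_batch,
)
from .volume import Volume3D

__all__ = [
    "TokenSequence", "FusionConfig", "MINI_FUSION_CONFIG", "FULL_FUSION_CONFIG",
    "MultiHeadSelfAttention", "TransformerLayer", "CrossAttentionFuse",
    "FusionClassifier", "tokenize", "scatter_back", "classify", "train_stage2",
    "quantised_grid", "quantised_grid_batch",
]


@dataclass
class TokenSequence:
    """(m+1)×d token matrix with exactly one class token (position 0)."""

    tokens: np.ndarray
    class_index: int = 0

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float64)
        if self.tokens.ndim != 2:
            raise ValueError("tokens must be a (m+1)×d matrix")

    @property
    def d(self) -> int:
        return self.tokens.shape[1]


@dataclass(frozen=True)
class FusionConfig:
    """Stage-2 architecture and training hyper-parameters."""

    d: int = 256                # token width (= codebook d)
    n_layers: int = 8           # alternating transformer + cross-attention
    n_heads: int = 8
    mlp_ratio: float = 2.0      # transformer feed-forward expansion
    n_conv_blocks: int = 3      # trainable residual blocks before tokenising
    groups: int = 2
    negative_slope: float = 0.01
    lr: float = 1e-4
    weight_decay: float = 0.05
    epochs: int = 200
    warmup_epochs: int = 20
    batch_size: int = 8
    dtype: str = "float32"   # training precision; oracle-facing maths is float64

    def __post_init__(self):
        if self.d % self.n_heads:
            raise ValueError(f"n_heads={self.n_heads} must divide d={self.d}")

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads


FULL_FUSION_CONFIG = FusionConfig()

#: Desk-scale profile: 32-wide tokens, 2 layers / 2 heads; short, hotter
#: schedule so the full stage-2 path trains on one CPU in minutes.
MINI_FUSION_CONFIG = FusionConfig(
    d=32, n_layers=2, n_heads=2, lr=1e-3, epochs=80, warmup_epochs=8,
    batch_size=15,
)


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    N, T, D = x.shape
    return x.reshape(N, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    N, h, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(N, T, h * dh)


def _attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(Q·Kᵀ/√d_head)·V on (N, h, T, d_head) tensors."""
    dh = q.shape[-1]
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    return scores.softmax(axis=-1) @ v


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide d={d}")
        self.n_heads = n_heads
        self.wq = Linear(d, d, rng, init="trunc_normal")
        self.wk = Linear(d, d, rng, init="trunc_normal")
        self.wv = Linear(d, d, rng, init="trunc_normal")
        self.wo = Linear(d, d, rng, init="trunc_normal")

    def forward(self, x: Tensor) -> Tensor:
        q = _split_heads(self.wq(x), self.n_heads)
        k = _split_heads(self.wk(x), self.n_heads)
        v = _split_heads(self.wv(x), self.n_heads)
        return self.wo(_merge_heads(_attention(q, k, v)))

    def attention_rows(self, x: np.ndarray) -> np.ndarray:
        """The (N, h, T, T) attention matrix, for diagnostics/tests."""
        xt = Tensor(x)
        q = _split_heads(self.wq(xt), self.n_heads)
        k = _split_heads(self.wk(xt), self.n_heads)
        dh = q.shape[-1]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        return scores.softmax(axis=-1).data


class TransformerLayer(Module):
    """Pre-norm residual MHSA + pre-norm residual feed-forward (ViT style)."""

    def __init__(self, config: FusionConfig, rng: np.random.Generator):
        d = config.d
        hidden = int(d * config.mlp_ratio)
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, config.n_heads, rng)
        self.norm2 = LayerNorm(d)
        self.fc1 = Linear(d, hidden, rng, init="trunc_normal")
        self.fc2 = Linear(hidden, d, rng, init="trunc_normal")
        self.negative_slope = config.negative_slope

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        h = self.fc2(self.fc1(self.norm2(x)).leaky_relu(self.negative_slope))
        return x + h


class CrossAttentionFuse(Module):
    """One stream's class token queries the other stream's patch tokens."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.wq = Linear(d, d, rng, init="trunc_normal")
        self.wk = Linear(d, d, rng, init="trunc_normal")
        self.wv = Linear(d, d, rng, init="trunc_normal")
        self.wo = Linear(d, d, rng, init="trunc_normal")

    def forward(self, class_token: Tensor, other_tokens: Tensor) -> Tensor:
        """class_token (N,1,D) attends over other_tokens (N,m,D); residual."""
        q = _split_heads(self.wq(class_token), self.n_heads)
        k = _split_heads(self.wk(other_tokens), self.n_heads)
        v = _split_heads(self.wv(other_tokens), self.n_heads)
        return class_token + self.wo(_merge_heads(_attention(q, k, v)))


def tokenize(
    grid_values: np.ndarray,
    class_token: np.ndarray,
    positional_encodings: np.ndarray | None = None,
) -> TokenSequence:
    """Flatten a (c,x,y,z) grid into m = x·y·z width-c tokens.

    Raster order is fixed: x fastest, then y, then z. The class token is
    concatenated at position 0; learned positional encodings (shape
    (m+1, c)) are added to every token including the class token.
    """
    grid_values = np.asarray(grid_values, dtype=np.float64)
    c = grid_values.shape[0]
    patches = grid_values.transpose(3, 2, 1, 0).reshape(-1, c)  # x fastest
    tokens = np.concatenate([np.asarray(class_token).reshape(1, c), patches])
    if positional_encodings is not None:
        pe = np.asarray(positional_encodings)
        if pe.shape != tokens.shape:
            raise ValueError(
                f"positional encodings {pe.shape} != token matrix {tokens.shape}"
            )
        tokens = tokens + pe
    return TokenSequence(tokens)


def scatter_back(seq: TokenSequence, spatial: tuple[int, int, int]) -> np.ndarray:
    """Inverse raster: patch tokens (class token dropped) back to (c,x,y,z)."""
    x, y, z = spatial
    patches = np.delete(seq.tokens, seq.class_index, axis=0)
    return patches.reshape(z, y, x, seq.d).transpose(3, 2, 1, 0)


class _Stream(Module):
    """Per-modality trainable stack: conv blocks, class token, PE, layers."""

    def __init__(self, config: FusionConfig, m: int, rng: np.random.Generator):
        d = config.d
        self.conv_blocks = [
            PreActBlock(d, d, (3, 3, 1), config.groups, config.negative_slope,
                        rng, init="trunc_normal")
            for _ in range(config.n_conv_blocks)
        ]
        self.class_token = Parameter(trunc_normal(rng, (d,)))
        self.pos_embed = Parameter(trunc_normal(rng, (m + 1, d)))
        self.layers = [TransformerLayer(config, rng) for _ in range(config.n_layers)]
        self.fusers = [
            CrossAttentionFuse(d, config.n_heads, rng) for _ in range(config.n_layers)
        ]


class FusionClassifier(Module):
    """The full stage-2 network over a pair of quantised latent grids."""

    def __init__(self, config: FusionConfig, grid_shape: tuple[int, int, int],
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.grid_shape = tuple(grid_shape)
        m = int(np.prod(grid_shape))
        self.t2_stream = _Stream(config, m, rng)
        self.adc_stream = _Stream(config, m, rng)
        d = config.d
        # head: concatenated class tokens (2d) -> d -> 3 logits
        self.head_fc1 = Linear(2 * d, d, rng, init="trunc_normal")
        self.head_fc2 = Linear(d, 3, rng, init="trunc_normal")
        self.astype(np.dtype(config.dtype))

    # ---------------------------------------------------------------- forward
    def _tokens(self, stream: _Stream, grids: Tensor) -> Tensor:
        """(N,x,y,z,c) quantised grids -> (N, m+1, d) position-encoded tokens."""
        h = grids
        for block in stream.conv_blocks:
            h = block(h)
        N, c = h.shape[0], h.shape[-1]
        patches = h.transpose(0, 3, 2, 1, 4).reshape(N, -1, c)  # raster, x fastest
        cls = stream.class_token.reshape(1, 1, -1) * Tensor(
            np.ones((N, 1, 1), dtype=stream.class_token.data.dtype)
        )
        tokens = concatenate([cls, patches], axis=1)
        return tokens + stream.pos_embed

    def forward(self, t2_grids: Tensor, adc_grids: Tensor) -> Tensor:
        """(N,x,y,z,c) channel-last grid batches -> (N, 3) logits."""
        a = self._tokens(self.t2_stream, t2_grids)
        b = self._tokens(self.adc_stream, adc_grids)
        for la, lb, fa, fb in zip(self.t2_stream.layers, self.adc_stream.layers,
                                  self.t2_stream.fusers, self.adc_stream.fusers):
            a, b = la(a), lb(b)
            a_cls, a_patch = a[:, 0:1, :], a[:, 1:, :]
            b_cls, b_patch = b[:, 0:1, :], b[:, 1:, :]
            # bidirectional exchange: each class token queries the other
            # stream's patch tokens; the fused token re-enters its stream
            new_a_cls = fa(a_cls, b_patch)
            new_b_cls = fb(b_cls, a_patch)
            a = concatenate([new_a_cls, a_patch], axis=1)
            b = concatenate([new_b_cls, b_patch], axis=1)
        fused = concatenate([a[:, 0, :], b[:, 0, :]], axis=1)  # (N, 2d)
        h = self.head_fc1(fused).leaky_relu(self.config.negative_slope)
        return self.head_fc2(h)

    def predict_proba(self, t2_grid: np.ndarray, adc_grid: np.ndarray) -> np.ndarray:
        """Probability vector for one (c,x,y,z) pair of quantised grids."""
        return self.predict_proba_batch(t2_grid[None], adc_grid[None])[0]

    def predict_proba_batch(self, t2_grids: np.ndarray,
                            adc_grids: np.ndarray) -> np.ndarray:
        """(N,c,x,y,z) grid stacks -> (N,3) probabilities."""
        dt = self.dtype
        to_cl = lambda g: np.ascontiguousarray(
            np.asarray(g).transpose(0, 2, 3, 4, 1)
        ).astype(dt)
        logits = self.forward(Tensor(to_cl(t2_grids)), Tensor(to_cl(adc_grids)))
        return logits.softmax(axis=-1).data.astype(np.float64)


def quantised_grid(volume: Volume3D, stage1: Stage1Model) -> np.ndarray:
    """encode → quantise, the frozen front end of classification."""
    latent = encode(volume, stage1.encoder)
    return quantise(latent, stage1.codebook).values


def quantised_grid_batch(volumes: list[Volume3D], stage1: Stage1Model) -> np.ndarray:
    """Batched encode → quantise; returns (N, c, x, y, z) float64 grids."""
    data = np.stack([v.data for v in volumes])
    latents = encode_batch(data, stage1.encoder).astype(np.float64)  # (N,x,y,z,c)
    C = latents.shape[-1]
    idx = _assign(latents.reshape(-1, C), stage1.codebook.codes)
    quant = stage1.codebook.codes[idx].reshape(latents.shape)
    return quant.transpose(0, 4, 1, 2, 3)


def classify(
    t2: Volume3D,
    adc: Volume3D,
    stage1: dict[str, Stage1Model],
    classifier: FusionClassifier,
) -> np.ndarray:
    """Full pipeline probability vector for one preprocessed case."""
    zt = quantised_grid(t2, stage1["t2"])
    za = quantised_grid(adc, stage1["adc"])
    return classifier.predict_proba(zt, za)


# ----------------------------------------------------------------- training
def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; equal class weighting."""
    lse = logits.logsumexp(axis=-1)  # (N,)
    picked = logits[np.arange(len(labels)), labels]
    return (lse - picked).mean()


def save_stage2(classifier: FusionClassifier, seed: int, path) -> None:
    """Checkpoint the stage-2 network with its config, grid shape and seed."""
    import json

    cfg = classifier.config
    blobs = {f"w/{k}": v for k, v in classifier.state_dict().items()}
    blobs["__meta__"] = np.frombuffer(json.dumps({
        "d": cfg.d, "n_layers": cfg.n_layers, "n_heads": cfg.n_heads,
        "mlp_ratio": cfg.mlp_ratio, "n_conv_blocks": cfg.n_conv_blocks,
        "groups": cfg.groups, "negative_slope": cfg.negative_slope,
        "dtype": cfg.dtype, "grid_shape": list(classifier.grid_shape),
        "seed": seed,
    }).encode(), dtype=np.uint8)
    np.savez(path, **blobs)


def load_stage2(path) -> tuple[FusionClassifier, int]:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = FusionConfig(
            d=meta["d"], n_layers=meta["n_layers"], n_heads=meta["n_heads"],
            mlp_ratio=meta["mlp_ratio"], n_conv_blocks=meta["n_conv_blocks"],
            groups=meta["groups"], negative_slope=meta["negative_slope"],
            dtype=meta["dtype"],
        )
        clf = FusionClassifier(cfg, tuple(meta["grid_shape"]), seed=meta["seed"])
        clf.load_state_dict({k[2:]: z[k] for k in z.files if k.startswith("w/")})
    return clf, meta["seed"]


def _clip_global_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(
        float(np.sum(p.grad.astype(np.float64) ** 2))
        for p in params if p.grad is not None
    ))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def train_stage2(
    dataset: list[tuple[np.ndarray, np.ndarray, int]],
    classifier: FusionClassifier,
    config: FusionConfig,
    seed: int,
    max_steps: int | None = None,
    val_data: list[tuple[np.ndarray, np.ndarray, int]] | None = None,
) -> list[dict]:
    """Optimise the stage-2 network on cached quantised grids.

    ``dataset`` holds (t2_grid, adc_grid, label) triples — the grids come
    from the frozen stage-1 front end, so they are computed once and the
    frozen parameters cannot drift by construction. AdamW with decoupled
    weight decay, gradient clipping (global norm 1), and a cosine schedule
    with linear warm-up, per the ViT training recipe. When ``val_data`` is
    given, the held-out cross-entropy is evaluated at every epoch end and
    the best checkpoint is installed after training: short desk-scale
    trajectories are chaotic, and selecting the best validated iterate is
    far more reproducible than keeping wherever the last step lands.
    Returns the loss history.
    """
    if not dataset:
        raise ValueError("empty stage-2 training set")
    rng = np.random.default_rng(seed)
    params = classifier.parameters()
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
    n = len(dataset)
    dt = np.dtype(config.dtype)
    to_cl = lambda gs: np.ascontiguousarray(
        np.stack(gs).transpose(0, 2, 3, 4, 1)
    ).astype(dt)
    t2 = to_cl([d[0] for d in dataset])
    adc = to_cl([d[1] for d in dataset])
    labels = np.array([d[2] for d in dataset], dtype=np.int64)
    if val_data:
        vt2 = to_cl([d[0] for d in val_data])
        vadc = to_cl([d[1] for d in val_data])
        vlabels = np.array([d[2] for d in val_data], dtype=np.int64)
    steps_per_epoch = max(1, n // config.batch_size)
    total_steps = max_steps if max_steps is not None else config.epochs * steps_per_epoch
    # warm-up keeps the configured epoch ratio even when max_steps caps
    # (or augmentation inflates) the schedule
    warmup = int(round(total_steps * config.warmup_epochs / max(1, config.epochs)))
    history: list[dict] = []
    step = 0
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    for epoch in range(10**9):
        order = rng.permutation(n)
        ep_loss, ep_correct, nb = 0.0, 0, 0
        for lo in range(0, n, config.batch_size):
            if step >= total_steps:
                break
            sel = order[lo:lo + config.batch_size]
            logits = classifier.forward(Tensor(t2[sel]), Tensor(adc[sel]))
            loss = _cross_entropy(logits, labels[sel])
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            loss.backward()
            _clip_global_norm(params, 1.0)
            opt.step(lr=cosine_warmup(step, total_steps, config.lr, warmup))
            ep_loss += float(loss.data)
            ep_correct += int((logits.data.argmax(axis=1) == labels[sel]).sum())
            nb += 1
            step += 1
        if nb:
            entry = {
                "epoch": epoch, "step": step, "loss": ep_loss / nb,
                "train_accuracy": ep_correct / min(n, nb * config.batch_size),
            }
            if val_data:
                vlogits = classifier.forward(Tensor(vt2), Tensor(vadc))
                vloss = float(_cross_entropy(vlogits, vlabels).data)
                entry["val_loss"] = vloss
                entry["val_accuracy"] = float(
                    (vlogits.data.argmax(axis=1) == vlabels).mean()
                )
                if vloss < best_val:
                    best_val = vloss
                    best_state = [p.data.copy() for p in params]
            history.append(entry)
        if step >= total_steps:
            break
    if best_state is not None:
        for p, saved in zip(params, best_state):
            p.data = saved
    return history
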