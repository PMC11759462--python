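# vqfusion

Robust 3-class lesion risk classification from paired anisotropic MR
volumes (a T2-weighted-like and an ADC-like channel), built on discrete
representations: a hybrid 2D/3D vector-quantised auto-encoder turns each
modality into codebook tokens, and a dual-stream transformer with
class-token cross-attention fuses the two token streams. Because the
classifier consumes only quantised latents, input corruptions too small to
flip any code assignment provably cannot change a prediction — the package
ships a corruption benchmark (Gaussian / Poisson / salt-and-pepper noise,
Gaussian blur, motion artefact) that quantifies this robustness.

It is aimed at researchers studying acquisition-shift robustness in
medical image classification (e.g. 1.5 T vs 3 T prostate mpMRI), and runs
entirely on synthetic paired phantoms, so no clinical data is needed to
exercise any part of the pipeline.

## The model

**Stage 1 — discrete representation.** Per modality, an encoder φ_e maps a
volume x to a continuous latent grid e ∈ R^{c×x×y×z}; each site fibre
e_i ∈ R^c is replaced by its nearest row of a learned codebook
D ∈ R^{K×d} (d = c),

    k = argmin_j ‖e_i − l_j‖₂ ,

giving the quantised grid ẑ decoded back by φ_d. Training minimises

    L = MSE(x̂, x) + Σ_i ‖sg(e_i) − l_k‖ + β Σ_i ‖e_i − sg(l_k)‖ ,  β = 0.25,

with straight-through gradients across the quantisation step (the
decoder-input gradient is copied to the encoder output). All pooling is
in-plane — the slice axis is never downsampled — matching the anisotropic
voxel geometry (0.5 × 0.5 × 1.5 mm).

**Stage 2 — fusion transformer.** With stage 1 frozen (encoders,
pre-quantisation blocks, both dictionaries), each modality's quantised
grid passes through three trainable pre-activation residual conv blocks,
is flattened into m = x·y·z tokens plus a class token with learned
positional encodings, and runs through its own transformer stream
(pre-norm MHSA, softmax(QKᵀ/√d_head)V per head). After every transformer
layer the streams exchange information: each class token forms a single
multi-head query over the other stream's patch tokens and is updated
residually. The final two class tokens are concatenated and an MLP head
produces the 3-class softmax (low / medium / high risk). Training uses
AdamW (weight decay 0.05) under a cosine schedule with linear warm-up and
equal-weight cross-entropy.

Evaluation is one-vs-rest per risk group (accuracy, specificity,
precision, recall, Mann–Whitney AUC) and, under the 25-setting corruption
grid, the relative corruption error

    RCE = 100 · mean_k(ΔAUC_ours,k) / mean_k(ΔAUC_ref,k) ,

where values below 100 mean the model loses less AUC than the reference.

## Worked example

Train the full two-stage pipeline on synthetic phantoms and evaluate with
corruption robustness (roughly a quarter of an hour on one CPU):

```
vqfusion run-perturbation --profile mini --seed 1 --out report.json
```

which prints (seed 1)

```
clean AUC 0.938; report -> report.json
```

and `report.json` holds the class-averaged AUC per corruption family for
the token model and the raw-voxel logistic-regression reference, plus the
RCE table; at seed 1:

| family (class-averaged AUC) | token model | raw-voxel reference |
|---|---|---|
| clean | 0.938 | — |
| gaussian | 0.707 | 0.884 |
| poisson | 0.761 | 0.862 |
| salt & pepper | 0.562 | 0.771 |
| blur | 0.950 | 0.931 |
| motion | 0.812 | 0.930 |

The clean AUC of 0.938 means the fused classifier ranks held-out phantom
cases per risk group almost perfectly. Under corruption the comparison
with this particular reference is instructive rather than flattering: the
phantom class signal is a mean lesion intensity, so a linear readout that
averages voxels is intrinsically immune to zero-mean noise, while noise
strong enough to flip code assignments does degrade the token model (its
RCE against the linear reference at seed 1 is well above 100). What the
discrete bottleneck *guarantees* — and the test suite verifies
constructively — is that perturbations too small to flip any nearest-code
assignment cannot change the prediction at all. (Numbers vary somewhat
with the seed; regenerate them with the command above.)

The same workflow is available step by step: `vqfusion make-phantoms`,
`train-stage1`, `train-stage2`, `predict`, `corrupt`, `evaluate`, and
`run-sdg` for the acquisition-shift (train domain A, test domain B)
design. Every command is a thin wrapper over the library API
(`vqfusion.workbench`, `vqfusion.fusion`, ...).

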