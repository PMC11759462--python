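# Methods

## Model

### Stage 1: per-modality vector-quantised auto-encoders

Each modality (pseudo-T2, pseudo-ADC) gets its own encoder–decoder–codebook
triple; nothing is shared, including the random streams used at
initialisation. The encoder is hybrid 2D/3D: a stack of pre-activation
residual blocks with 3×3×1 kernels, each followed by 2×2 in-plane
max-pooling, then one non-downsampling 3×3×3 block that mixes adjacent
slices and widens the features to the codebook dimensionality d (the
"pre-quantisation block" that is frozen in stage 2). The slice axis is
never pooled: thick-slice MR has 3× coarser spacing through-plane, and
pooling it would destroy the few slices available. The decoder mirrors the
encoder with bilinear in-plane upsampling. Blocks are
GroupNorm(2) → LeakyReLU(0.01) → conv, twice, with an additive shortcut
(1×1×1 projection when widths change).

Quantisation snaps every latent fibre to its Euclidean-nearest codebook
row, ties to the lowest index (deterministic and oracle-checkable). The
argmin uses squared distances computed directly as Σ(e−l)² — not the
expanded ‖e‖²−2e·l+‖l‖² identity — so floating-point ties behave exactly
like a per-pair reference loop. Codebooks initialise uniformly on
[−1/K, 1/K]; the default dictionary size is K = 128, the smallest size
that drives reconstruction MSE below 10⁻³ on the smooth-phantom benchmark
(see `stage1_capacity_check`).

The training objective combines voxel-mean reconstruction MSE, a codebook
term pulling each assigned row toward its (stop-gradient) fibres, and a
β-weighted commitment term (β = 0.25) pulling fibres toward their
(stop-gradient) rows; gradients cross the quantisation step by the
straight-through convention. Two deliberate choices here:

* **Squared-distance training terms.** The reported loss decomposition
  (`vqfusion.quantiser.vq_losses`) uses unsquared site norms
  Σᵢ‖·‖₂. For *training*, the codebook/commitment terms use the squared
  form as per-site means. The unsquared norm has a constant-magnitude
  gradient (a unit vector), which at desk scale locks every fibre onto the
  first code that wins an assignment and collapses the dictionary onto one
  or two rows; the squared form's gradient vanishes near the assigned code
  and trains stably with the same β.
* **Dead-code reseeding.** Codes unused for `reseed_every` (default 50)
  consecutive steps are restarted at random encoder fibres of the current
  batch. Nearest-neighbour assignment plus the codebook term is a k-means
  style dynamic: it can move a code to the mean of its cluster but can
  never split a code serving several clusters, so without reseeding,
  low-diversity data (e.g. constant volumes) ends with two live codes and
  indistinguishable intensity levels. Reseeding is disableable
  (`reseed_every=0`).

Convolutions replicate-pad their borders so spatially constant inputs map
to constant outputs; residual branches start at zero (second conv
zero-initialised) with gain-1 projection shortcuts, so every block is the
identity at initialisation — without this, the randomly scaled shortcut
chain multiplies the signal ~30× and the first hundred steps of a short
fit are spent undoing the initialisation.

### Stage 2: dual-stream fusion transformer

The quantised grids pass through three trainable pre-activation blocks
(3×3×1, no weight sharing between modalities), are flattened in fixed
raster order (x fastest, then y, then z) into m = x·y·z tokens, and a
learned class token is prepended with learned per-position encodings
(one set per stream). Each stream runs pre-norm transformer layers
(MHSA with softmax(QKᵀ/√d_head)V per head; feed-forward expansion 2,
leaky-ReLU). After every transformer layer, bidirectional class-token
cross-attention exchanges information: the T2 class token forms a single
query over the ADC patch tokens (8 heads at full scale), the attended
value is added residually, and the fused token re-enters its stream for
the next layer; symmetrically ADC→T2. After the final layer the two class
tokens are concatenated (width 2d) and an MLP (2d → d → 3, leaky-ReLU)
produces logits.

Stage-1 parameters are frozen by construction: stage-2 training consumes
cached quantised grids and its optimiser only ever sees stage-2
parameters; the test suite asserts bit-exact equality of every stage-1
array and both codebooks across training.

Stage-2 weights use a variance-preserving truncated normal
(±2σ, σ = 1/√fan_in). A fixed σ = 0.02 — the convention for large-scale
vision-transformer pre-training — leaves the class token's pathway so
attenuated at these widths that a few-hundred-step fit never escapes the
uniform-prediction plateau; σ = 1/√fan_in preserves activation variance
and trains immediately. A consequence of the strong initialisation is
that the untrained network is only approximately uniform: the first-batch
cross-entropy sits near, not at, ln 3. Optimisation is AdamW (decoupled
weight decay 0.05, applied to all parameters — at this data scale,
decaying norms and embeddings measurably improves generalisation) under
cosine annealing with linear warm-up, cross-entropy with equal class
weights. Stage-2 training applies the protocol's spatial augmentation:
each training case contributes flip-and-rotate variants (the same
transform to both modalities) re-encoded through the frozen stage-1 front
end, with the optimisation budget held at the unaugmented schedule;
without it, the transformer memorises background texture and
generalisation across held-out cases degrades sharply.

### Profiles

| parameter | full profile | mini profile |
|---|---|---|
| patch size | 128×128×8 | 32×32×4 |
| 2-D blocks (channels) | 3 (32, 64, 128) | 2 (8, 16) |
| latent width d | 256 | 32 |
| codebook K | 128 | 128 |
| latent grid | 16×16×8 | 8×8×4 (m = 256) |
| transformer | 8 layers, 8 heads | 2 layers, 2 heads |
| stage 1 | Adam, lr 5e-4, wd 0.01, 200 epochs | lr 2e-3, ≤500 steps (≤1500 for the capacity study, plateau-stopped) |
| stage 2 | AdamW, lr 1e-4, 200 epochs, 20 warm-up | lr 1e-3, 80 epochs, 8 warm-up |

The mini profile exists so the complete two-stage workflow — stage-1
training, stage-2 training, and the 25-setting corruption benchmark —
runs on one CPU in minutes. Training runs in float32; the public API and
all oracle-facing computations are float64.

## Synthetic data

`vqfusion.synthetic_data` generates paired pseudo-T2/pseudo-ADC phantoms:
an ellipsoidal gland (intensity 0.5 against a 0.15 background), a smooth
random background texture (amplitude 0.16, Gaussian correlation lengths
2.0 voxels in-plane / 0.5 through-plane), and one ellipsoidal lesion near
the volume centre — the inputs emulate lesion-centred crops, as produced
by the preprocessing pipeline — whose mean intensity is class-dependent.
In the ADC channel the class means decrease strictly with grade
(low 0.75, medium 0.55, high 0.35, per-case jitter σ = 0.03), emulating
diffusion restriction increasing with aggressiveness; the T2 channel
carries a weaker parallel trend (0.62/0.54/0.46). A `contrast_gap` knob
scales the gaps about the medium level, making class separability tunable
and monotone.

The `domain` knob (A/B) emulates acquisition shift: domain B applies a
global contrast scale 0.85, a higher noise floor (σ 0.04 vs 0.02) and a
mild in-plane blur (σ 0.6 voxels). Domains never differ in geometry or in
the class-conditional ordering — the shift is purely covariate, which is
the premise of the single-domain-generalisation design. Re-rendering the
same master seed in either domain reproduces identical lesion masks.

The texture parameters were set so that the codebook-capacity story holds
at desk scale: 16 codes cannot reconstruct the texture below MSE 10⁻³
while 128 codes can. The `smooth_phantom_volumes` helper emits the same
phantoms with the additive acquisition noise switched off — the
reconstruction benchmark measures codebook capacity, not denoising.

What the phantoms do **not** emulate: MRI physics (k-space acquisition,
bias fields, b-value dependence), anatomy (zonal structure, multiple or
irregular lesions), inter-site protocol variability beyond the two
synthetic domains, and label noise. Passing results therefore verify the
*mechanism* — codebook learning, discrete-token fusion, corruption
robustness — not clinical performance.

## Corruption protocol

Three noise families at seven levels (1, 5, 10, 15, 20, 25, 30 %), blur at
three variances (0.1, 1.0, 2.0; 7×7 in-plane kernel), and one motion
setting: 25 settings. The "%" semantics are conventions of this package
(the families are standard, their level scales are not): Gaussian noise
uses σ = level on the [0,1] scale; Poisson replaces each voxel by
Poisson(v·λ)/λ with λ = 1/level² so relative noise grows with level;
salt-and-pepper sets a `level` fraction of voxels to 0 or 1. Motion is a
k-space line-replacement model: a random 35 % of in-plane frequency lines
are taken from a rigidly displaced copy (translation ≤ 3 voxels, rotation
≤ 5°). Every stochastic family is seed-reproducible; every output is
clipped to [0,1].

The benchmark's RCE reference model is a multinomial logistic regression
on 2× downsampled raw voxels of both modalities (no discrete bottleneck,
no attention). RCE is reported in both orientations plus the raw ratio,
since the ratio's direction is a reporting convention. One caveat read
directly off the phantom design: the class signal is a mean lesion
intensity, and a linear voxel-averaging readout is intrinsically robust
to zero-mean noise, so at desk scale the discrete-token model does not
necessarily beat this particular reference under heavy corruption — the
discreteness mechanism guarantees absorption of perturbations too small
to flip any code assignment (verified constructively in the test suite),
not robustness to arbitrary noise levels. Clinical-scale comparisons
against deep CNN/ViT baselines are a different regime.

## Evaluation

Per risk group, the 3-class problem is binarised one-vs-rest: confusion
metrics at the argmax prediction, AUC from the group's probability column
as the Mann–Whitney statistic (ties half; verified against exhaustive
pair enumeration and scikit-learn). Class-averaged metrics are unweighted
means; overall top-1 accuracy is logged alongside. Absent classes yield
NaN metrics, are excluded from averages, and warn.

## Numerical notes and limitations

* Nearest-code ties go to the lowest index everywhere.
* `rescale_intensity` maps constant volumes to zeros (with a warning)
  rather than dividing by zero.
* The l2-norm terms in the reported loss carry a 1e-12 epsilon under the
  square root so the gradient at exactly zero distance is defined.
* Resampling clamps samples beyond the last voxel centre to the edge
  value (nearest-neighbour extrapolation) instead of zero-filling.
* The stage-2 routing choice — the fused class token replaces the
  stream's class token before the next transformer layer — is one of two
  defensible readings of the alternating-layer design; it is the one that
  lets fusion depth compound.
* Training the NumPy engine is single-threaded BLAS-bound; the full-scale
  profile is configured but sized for GPU-class budgets, and the shipped
  experiments all use the mini profile.
* With 10 test cases per class, per-class AUCs move in steps of 1/200;
  seed-to-seed variation of benchmark numbers is expected and the
  workbench reports mean ± s.d. across a seed list where more stability
  is needed.
* Capacity monotonicity (reconstruction error non-increasing in K) is a
  statement about converged models; at the mini profile's few-hundred-step
  budget the K = 128 vs K = 16 ordering carries optimisation noise and can
  invert for some seeds, while the K = 128 error itself stays below 10⁻³
  across the seeds examined.
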