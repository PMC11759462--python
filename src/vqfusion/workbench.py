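"""Experiment orchestration: acquisition-shift and perturbation benchmarks.

Two desk-scale experiment designs over synthetic paired phantoms:

* ``sdg`` (single-domain generalisation): train the full two-stage model
  on one acquisition domain, evaluate on the other, in both directions,
  and average — probing robustness to covariate shift.
* ``perturbation``: train and test within one domain (30/10 cases per risk
  group by default), then evaluate the clean test set and a 25-setting
  corruption grid (3 noise families × 7 levels, 3 blur variances, 1
  motion), reporting per-family AUC summaries and the relative corruption
  error against a reference model.

The RCE reference model is a raw-intensity multinomial logistic
regression on downsampled voxels — no discrete bottleneck, no attention.
Note that on phantoms whose class signal is a mean intensity, linear
voxel averaging is itself highly noise-robust, so the RCE direction
against this reference is an empirical question, not a foregone
conclusion; both orientations are reported.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import __version__
from .evaluation import (
    CLASSES, MetricReport, PredictionSet, one_vs_rest_metrics,
    relative_corruption_error,
)
from .fusion import (
    FusionClassifier, FusionConfig, MINI_FUSION_CONFIG, FULL_FUSION_CONFIG,
    quantised_grid, quantised_grid_batch, train_stage2,
)
from .perturbations import PerturbationSpec, apply_perturbation, protocol_grid
from .synthetic_data import Case, generate_dataset
from .vqvae import (
    MINI_CONFIG, FULL_CONFIG, Stage1Model, VqVaeConfig, train_stage1,
)

__all__ = [
    "ExperimentConfig", "TrainedPipeline", "train_pipeline", "evaluate_cases",
    "run_sdg_experiment", "run_perturbation_benchmark", "RawVoxelBaseline",
    "stage1_capacity_check",
]

_LABEL_TO_INT = {c: i for i, c in enumerate(CLASSES)}

_PROFILES: dict[str, tuple[VqVaeConfig, FusionConfig, tuple[int, int, int]]] = {
    "mini": (MINI_CONFIG, MINI_FUSION_CONFIG, (32, 32, 4)),
    "full": (FULL_CONFIG, FULL_FUSION_CONFIG, (128, 128, 8)),
}


@dataclass(frozen=True)
class ExperimentConfig:
    mode: str = "perturbation"            # "sdg" or "perturbation"
    profile: str = "mini"
    train_domain: str = "A"
    test_domain: str = "B"
    n_train_per_class: int = 30
    n_test_per_class: int = 10
    seed: int = 0
    stage1_steps: int | None = 500        # None = profile's epoch budget
    stage2_steps: int | None = None
    contrast_gap: float = 1.0

    def __post_init__(self):
        if self.mode not in ("sdg", "perturbation"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile '{self.profile}'")
        if self.mode == "sdg" and self.train_domain == self.test_domain:
            raise ValueError("sdg mode requires train domain != test domain")

    def provenance(self) -> dict:
        blob = json.dumps(asdict(self), sort_keys=True)
        return {
            "config": asdict(self),
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "version": __version__,
        }


@dataclass
class TrainedPipeline:
    stage1: dict[str, Stage1Model]
    classifier: FusionClassifier
    vq_config: VqVaeConfig
    fusion_config: FusionConfig
    stage2_history: list[dict]


def train_pipeline(
    train_cases: list[Case],
    vq_config: VqVaeConfig,
    fusion_config: FusionConfig,
    seed: int,
    stage1_steps: int | None = None,
    stage2_steps: int | None = None,
    n_augment: int = 3,
    val_fraction: float = 1 / 6,
) -> TrainedPipeline:
    """Stage 1 (per-modality VQ-VAEs) then stage 2 (fusion classifier).

    Stage-2 training follows the protocol: spatial augmentation (each
    training case additionally contributes ``n_augment`` flip-and-rotate
    variants, the same transform to both modalities, re-encoded through
    the frozen stage-1 front end) and best-checkpoint selection on a
    stratified validation split carved from the training cases
    (``val_fraction`` per class; validation cases are excluded from
    training and augmentation). The optimisation step budget is held at
    the unaugmented full-set schedule, so augmentation adds diversity,
    not wall time.
    """
    from .preprocess import augment

    stage1 = train_stage1(
        {"t2": [c.t2 for c in train_cases], "adc": [c.adc for c in train_cases]},
        vq_config, seed=seed, max_steps=stage1_steps,
    )
    # stratified validation split (last fraction of each class, stable order)
    by_class: dict[str, list[Case]] = {}
    for c in train_cases:
        by_class.setdefault(c.label, []).append(c)
    fit_cases, val_cases = [], []
    for label, cases in sorted(by_class.items()):
        n_val = max(1, int(round(val_fraction * len(cases)))) if val_fraction else 0
        fit_cases.extend(cases[:len(cases) - n_val])
        val_cases.extend(cases[len(cases) - n_val:])
    pairs = [(c.t2, c.adc, _LABEL_TO_INT[c.label]) for c in fit_cases]
    for k in range(n_augment):
        for i, c in enumerate(fit_cases):
            t2a, adca = augment((c.t2, c.adc), seed=seed * 100003 + k * 1009 + i)
            pairs.append((t2a, adca, _LABEL_TO_INT[c.label]))
    zt = quantised_grid_batch([p[0] for p in pairs], stage1["t2"])
    za = quantised_grid_batch([p[1] for p in pairs], stage1["adc"])
    grids = [(zt[i], za[i], pairs[i][2]) for i in range(len(pairs))]
    val_grids = None
    if val_cases:
        vzt = quantised_grid_batch([c.t2 for c in val_cases], stage1["t2"])
        vza = quantised_grid_batch([c.adc for c in val_cases], stage1["adc"])
        val_grids = [
            (vzt[i], vza[i], _LABEL_TO_INT[c.label])
            for i, c in enumerate(val_cases)
        ]
    grid_shape = grids[0][0].shape[1:]
    classifier = FusionClassifier(fusion_config, grid_shape, seed=seed + 1)
    if stage2_steps is None:
        # budget as if unaugmented: epochs × (n_cases / batch)
        stage2_steps = fusion_config.epochs * max(
            1, len(train_cases) // fusion_config.batch_size
        )
    history = train_stage2(grids, classifier, fusion_config, seed=seed + 2,
                           max_steps=stage2_steps, val_data=val_grids)
    return TrainedPipeline(stage1, classifier, vq_config, fusion_config, history)


def stage1_capacity_check(
    seed: int,
    codebook_sizes: tuple[int, ...] = (128, 16),
    n_volumes: int = 40,
    shape: tuple[int, int, int] = (32, 32, 4),
    max_steps: int = 1500,
) -> dict[int, float]:
    """Train mini VQ-VAEs on smooth phantoms, one per codebook size.

    Shared data and seed across the codebook sizes; each run stops at its
    reconstruction plateau (or the step cap). Returns the final
    reconstruction MSE over the training volumes per codebook size — the
    capacity curve whose K=128 point the dictionary size was chosen by.
    """
    from dataclasses import replace

    from .synthetic_data import smooth_phantom_volumes
    from .vqvae import reconstruction_mse

    volumes = smooth_phantom_volumes(n_volumes, shape=shape, seed=seed)
    out: dict[int, float] = {}
    for K in codebook_sizes:
        cfg = replace(MINI_CONFIG, K=K, plateau_patience=20)
        models = train_stage1({"t2": volumes}, cfg, seed=seed, max_steps=max_steps)
        out[K] = reconstruction_mse(models["t2"], volumes)
    return out


def _predict_cases(pipeline: TrainedPipeline, cases: list[Case],
                   spec: PerturbationSpec | None) -> PredictionSet:
    t2s, adcs = [], []
    for i, case in enumerate(cases):
        t2, adc = case.t2, case.adc
        if spec is not None and spec.kind != "none":
            t2 = apply_perturbation(
                t2, PerturbationSpec(spec.kind, spec.level, seed=spec.seed + 2 * i)
            )
            adc = apply_perturbation(
                adc, PerturbationSpec(spec.kind, spec.level, seed=spec.seed + 2 * i + 1)
            )
        t2s.append(t2)
        adcs.append(adc)
    zt = quantised_grid_batch(t2s, pipeline.stage1["t2"])
    za = quantised_grid_batch(adcs, pipeline.stage1["adc"])
    scores = pipeline.classifier.predict_proba_batch(zt, za)
    return PredictionSet(
        case_ids=[c.case_id for c in cases],
        labels=np.array([_LABEL_TO_INT[c.label] for c in cases]),
        scores=scores,
        perturbation="none" if spec is None else spec.tag,
    )


def evaluate_cases(pipeline: TrainedPipeline, cases: list[Case],
                   spec: PerturbationSpec | None = None) -> MetricReport:
    return one_vs_rest_metrics(_predict_cases(pipeline, cases, spec))


class RawVoxelBaseline:
    """Multinomial logistic regression on downsampled raw voxels.

    The RCE reference: no discrete bottleneck and no attention, every
    corrupted voxel feeds the decision directly. Because its linear
    weights average over many voxels, zero-mean noise largely cancels —
    on mean-intensity class signals this reference is itself hard to
    corrupt, which the robustness comparison must be read against.
    """

    def __init__(self, downsample: int = 2, seed: int = 0):
        self.downsample = downsample
        self.model = LogisticRegression(max_iter=2000, random_state=seed)

    def _features(self, cases_or_pair) -> np.ndarray:
        feats = []
        for case in cases_or_pair:
            s = self.downsample
            t2 = case.t2.data[::s, ::s, :]
            adc = case.adc.data[::s, ::s, :]
            feats.append(np.concatenate([t2.ravel(), adc.ravel()]))
        return np.asarray(feats)

    def fit(self, cases: list[Case]) -> "RawVoxelBaseline":
        y = np.array([_LABEL_TO_INT[c.label] for c in cases])
        self.model.fit(self._features(cases), y)
        return self

    def predict(self, cases: list[Case],
                spec: PerturbationSpec | None = None) -> PredictionSet:
        if spec is not None and spec.kind != "none":
            from dataclasses import replace as dc_replace

            cases = [
                dc_replace(
                    c,
                    t2=apply_perturbation(
                        c.t2, PerturbationSpec(spec.kind, spec.level, spec.seed + 2 * i)
                    ),
                    adc=apply_perturbation(
                        c.adc, PerturbationSpec(spec.kind, spec.level, spec.seed + 2 * i + 1)
                    ),
                )
                for i, c in enumerate(cases)
            ]
        proba = self.model.predict_proba(self._features(cases))
        full = np.zeros((len(cases), 3))
        full[:, self.model.classes_] = proba
        full /= full.sum(axis=1, keepdims=True)
        return PredictionSet(
            case_ids=[c.case_id for c in cases],
            labels=np.array([_LABEL_TO_INT[c.label] for c in cases]),
            scores=full,
            perturbation="none" if spec is None else spec.tag,
        )


def _check_leakage(train_cases: list[Case], test_cases: list[Case]) -> None:
    overlap = {c.case_id for c in train_cases} & {c.case_id for c in test_cases}
    if overlap:
        raise RuntimeError(f"train/test case-id leakage: {sorted(overlap)[:5]}")


def run_sdg_experiment(config: ExperimentConfig) -> dict:
    """Train on one domain, test on the other, both directions, averaged."""
    if config.mode != "sdg":
        raise ValueError("config.mode must be 'sdg'")
    vq_cfg, fu_cfg, shape = _PROFILES[config.profile]
    directions = {}
    for tag, (src, dst) in {
        "forward": (config.train_domain, config.test_domain),
        "reverse": (config.test_domain, config.train_domain),
    }.items():
        train_cases, _ = generate_dataset(
            config.n_train_per_class, domain=src, seed=config.seed,
            shape=shape, contrast_gap=config.contrast_gap,
        )
        test_cases, _ = generate_dataset(
            config.n_test_per_class, domain=dst, seed=config.seed + 10_000,
            shape=shape, contrast_gap=config.contrast_gap,
        )
        _check_leakage(train_cases, test_cases)
        pipeline = train_pipeline(
            train_cases, vq_cfg, fu_cfg, seed=config.seed,
            stage1_steps=config.stage1_steps, stage2_steps=config.stage2_steps,
        )
        directions[tag] = {
            "train_domain": src,
            "test_domain": dst,
            "report": evaluate_cases(pipeline, test_cases),
        }
    avg = {
        m: float(np.mean([
            directions[t]["report"].averaged[m] for t in directions
        ]))
        for m in directions["forward"]["report"].averaged
    }
    return {**config.provenance(), "directions": directions, "averaged": avg}


def run_perturbation_benchmark(
    config: ExperimentConfig,
    pipeline: TrainedPipeline | None = None,
) -> dict:
    """Clean + 25-corruption evaluation with family summaries and RCE."""
    vq_cfg, fu_cfg, shape = _PROFILES[config.profile]
    train_cases, _ = generate_dataset(
        config.n_train_per_class, domain=config.train_domain, seed=config.seed,
        shape=shape, contrast_gap=config.contrast_gap,
    )
    test_cases, _ = generate_dataset(
        config.n_test_per_class, domain=config.train_domain,
        seed=config.seed + 10_000, shape=shape, contrast_gap=config.contrast_gap,
    )
    _check_leakage(train_cases, test_cases)
    if pipeline is None:
        pipeline = train_pipeline(
            train_cases, vq_cfg, fu_cfg, seed=config.seed,
            stage1_steps=config.stage1_steps, stage2_steps=config.stage2_steps,
        )
    baseline = RawVoxelBaseline(seed=config.seed).fit(train_cases)

    grid = protocol_grid(seed=config.seed + 77)
    clean = evaluate_cases(pipeline, test_cases, None)
    clean_base = one_vs_rest_metrics(baseline.predict(test_cases, None))
    settings = {}
    for spec in grid:
        ours = evaluate_cases(pipeline, test_cases, spec)
        other = one_vs_rest_metrics(baseline.predict(test_cases, spec))
        settings[spec.tag] = {"spec": spec, "ours": ours, "baseline": other}

    families: dict[str, dict] = {}
    for kind in ("gaussian", "poisson", "salt_pepper", "blur", "motion"):
        members = [v for k, v in settings.items() if k.startswith(kind + "@")]
        if not members:
            raise RuntimeError(f"corruption family '{kind}' has no settings")
        families[kind] = {
            "n_settings": len(members),
            "auc_ours": {
                c: float(np.mean([m["ours"].per_class[c]["auc"] for m in members]))
                for c in CLASSES
            },
            "auc_ours_averaged": float(
                np.mean([m["ours"].averaged["auc"] for m in members])
            ),
            "auc_baseline_averaged": float(
                np.mean([m["baseline"].averaged["auc"] for m in members])
            ),
        }

    rce = {}
    for cname in CLASSES:
        ours_pert = [v["ours"].per_class[cname]["auc"] for v in settings.values()]
        base_pert = [v["baseline"].per_class[cname]["auc"] for v in settings.values()]
        rce[cname] = relative_corruption_error(
            clean.per_class[cname]["auc"], ours_pert,
            clean_base.per_class[cname]["auc"], base_pert,
        )
    ours_avg_pert = [v["ours"].averaged["auc"] for v in settings.values()]
    if not np.isclose(np.mean(clean.averaged["auc"] - np.array(ours_avg_pert)), 0.0):
        rce["self_check"] = relative_corruption_error(
            clean.averaged["auc"], ours_avg_pert,
            clean.averaged["auc"], ours_avg_pert,
        )

    return {
        **config.provenance(),
        "pipeline": pipeline,
        "clean": clean,
        "clean_baseline": clean_base,
        "settings": settings,
        "families": families,
        "rce": rce,
    }
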