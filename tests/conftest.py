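"""Shared fixtures: tiny phantoms and a quickly trained mini pipeline.

The "tiny" profile (16×16×4 volumes, 2 downsampling blocks → 4×4×4 latent
grids) exists purely so interface-level tests of the two-stage pipeline
run in seconds; convergence-sensitive checks use the mini profile in the
acceptance suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from vqfusion.fusion import MINI_FUSION_CONFIG, FusionConfig
from vqfusion.synthetic_data import PhantomSpec, generate_case, generate_dataset
from vqfusion.vqvae import MINI_CONFIG, VqVaeConfig, train_stage1

TINY_SHAPE = (16, 16, 4)

TINY_VQ_CONFIG = replace(MINI_CONFIG, channels=(8, 16), latent_channels=16)

TINY_FUSION_CONFIG = replace(
    MINI_FUSION_CONFIG, d=16, n_heads=2, n_layers=2, batch_size=6, epochs=10,
    warmup_epochs=1,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cases():
    cases, _ = generate_dataset(4, domain="A", seed=11, shape=TINY_SHAPE)
    return cases


@pytest.fixture(scope="session")
def tiny_stage1(tiny_cases):
    """A briefly trained pair of per-modality VQ-VAEs (interface-grade)."""
    return train_stage1(
        {"t2": [c.t2 for c in tiny_cases], "adc": [c.adc for c in tiny_cases]},
        TINY_VQ_CONFIG, seed=5, max_steps=25,
    )
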