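"""Stage-2 fusion transformer: attention oracles, tokenisation, freezing."""

from dataclasses import replace

import numpy as np
import pytest

from tests.conftest import TINY_FUSION_CONFIG
from vqfusion.fusion import (
    CrossAttentionFuse, FusionClassifier, FusionConfig, MultiHeadSelfAttention,
    TokenSequence, TransformerLayer, classify, quantised_grid,
    scatter_back, tokenize, train_stage2,
)
from vqfusion.nn import Tensor
from vqfusion.perturbations import PerturbationSpec, apply_perturbation
from vqfusion.quantiser import quantise
from vqfusion.vqvae import encode


def brute_force_attention(x, wq, bq, wk, bk, wv, bv, n_heads):
    """Single-loop attention oracle over an (T, d) token matrix."""
    T, d = x.shape
    dh = d // n_heads
    q, k, v = x @ wq + bq, x @ wk + bk, x @ wv + bv
    out = np.zeros((T, d))
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        qs, ks, vs = q[:, sl], k[:, sl], v[:, sl]
        for i in range(T):
            scores = np.array([qs[i] @ ks[j] / np.sqrt(dh) for j in range(T)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            out[i, sl] = sum(w[j] * vs[j] for j in range(T))
    return out


class TestMhsa:
    def test_single_token_returns_its_value_projection(self, rng):
        m = MultiHeadSelfAttention(8, 2, rng)
        x = rng.normal(size=(1, 1, 8))
        out = m(Tensor(x)).data
        expected = (x @ m.wv.weight.data + m.wv.bias.data) @ m.wo.weight.data \
            + m.wo.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_two_identical_tokens_attend_half_half(self, rng):
        m = MultiHeadSelfAttention(8, 2, rng)
        tok = rng.normal(size=8)
        rows = m.attention_rows(np.stack([tok, tok])[None])
        np.testing.assert_allclose(rows, 0.5, atol=1e-12)

    @pytest.mark.parametrize("n_heads,T", [(1, 5), (2, 6), (2, 8)])
    def test_matches_brute_force_oracle(self, rng, n_heads, T):
        d = 8
        m = MultiHeadSelfAttention(d, n_heads, rng)
        x = rng.normal(size=(T, d))
        expected = brute_force_attention(
            x, m.wq.weight.data, m.wq.bias.data, m.wk.weight.data,
            m.wk.bias.data, m.wv.weight.data, m.wv.bias.data, n_heads,
        ) @ m.wo.weight.data + m.wo.bias.data
        np.testing.assert_allclose(m(Tensor(x[None])).data[0], expected, atol=1e-8)

    def test_attention_rows_sum_to_one(self, rng):
        m = MultiHeadSelfAttention(16, 4, rng)
        rows = m.attention_rows(rng.normal(size=(2, 7, 16)))
        np.testing.assert_allclose(rows.sum(axis=-1), 1.0, atol=1e-6)

    def test_indivisible_width_rejected(self, rng):
        with pytest.raises(ValueError):
            MultiHeadSelfAttention(9, 2, rng)


class TestTransformerLayer:
    def test_shape_preserved(self, rng):
        layer = TransformerLayer(TINY_FUSION_CONFIG, rng)
        for T in (1, 4, 9):
            x = rng.normal(size=(2, T, 16))
            assert layer(Tensor(x)).shape == x.shape

    def test_zeroed_output_projections_give_identity(self, rng):
        layer = TransformerLayer(TINY_FUSION_CONFIG, rng)
        layer.attn.wo.weight.data[:] = 0
        layer.attn.wo.bias.data[:] = 0
        layer.fc2.weight.data[:] = 0
        layer.fc2.bias.data[:] = 0
        x = rng.normal(size=(1, 5, 16))
        np.testing.assert_allclose(layer(Tensor(x)).data, x, atol=1e-12)

    def test_permutation_equivariance_without_positional_encodings(self, rng):
        layer = TransformerLayer(TINY_FUSION_CONFIG, rng)
        x = rng.normal(size=(1, 6, 16))
        perm = np.array([0, 3, 1, 5, 2, 4])  # class token (0) stays put
        out = layer(Tensor(x)).data
        out_perm = layer(Tensor(x[:, perm])).data
        np.testing.assert_allclose(out[:, perm], out_perm, atol=1e-10)


class TestCrossAttention:
    def test_identical_keys_give_weight_free_output(self, rng):
        f = CrossAttentionFuse(8, 2, rng)
        cls = rng.normal(size=(1, 1, 8))
        tok = rng.normal(size=8)
        others = np.broadcast_to(tok, (1, 5, 8)).copy()
        out = f(Tensor(cls), Tensor(others)).data
        attended = (tok @ f.wv.weight.data + f.wv.bias.data) @ f.wo.weight.data \
            + f.wo.bias.data
        np.testing.assert_allclose(out, cls + attended, atol=1e-10)

    def test_single_key_case(self, rng):
        f = CrossAttentionFuse(8, 1, rng)
        cls = rng.normal(size=(1, 1, 8))
        other = rng.normal(size=(1, 1, 8))
        out = f(Tensor(cls), Tensor(other)).data
        attended = (other[0, 0] @ f.wv.weight.data + f.wv.bias.data) \
            @ f.wo.weight.data + f.wo.bias.data
        np.testing.assert_allclose(out, cls + attended, atol=1e-10)

    def test_matches_brute_force_single_query_oracle(self, rng):
        d, n_heads = 8, 2
        f = CrossAttentionFuse(d, n_heads, rng)
        cls = rng.normal(size=(1, 1, d))
        others = rng.normal(size=(1, 6, d))
        dh = d // n_heads
        q = cls[0] @ f.wq.weight.data + f.wq.bias.data
        k = others[0] @ f.wk.weight.data + f.wk.bias.data
        v = others[0] @ f.wv.weight.data + f.wv.bias.data
        attended = np.zeros(d)
        for h in range(n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            scores = np.array([q[0, sl] @ k[j, sl] / np.sqrt(dh) for j in range(6)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            attended[sl] = sum(w[j] * v[j, sl] for j in range(6))
        expected = cls[0, 0] + attended @ f.wo.weight.data + f.wo.bias.data
        np.testing.assert_allclose(f(Tensor(cls), Tensor(others)).data[0, 0],
                                   expected, atol=1e-8)


class TestTokenise:
    def test_full_scale_token_count(self, rng):
        grid = rng.normal(size=(256, 16, 16, 12))
        seq = tokenize(grid, np.zeros(256))
        assert seq.tokens.shape == (3073, 256)

    def test_small_grid_count(self, rng):
        seq = tokenize(rng.normal(size=(32, 2, 2, 1)), np.zeros(32))
        assert seq.tokens.shape == (5, 32)

    def test_raster_order_x_fastest(self):
        grid = np.arange(3 * 2 * 1).reshape(1, 3, 2, 1).astype(float)
        seq = tokenize(grid, np.zeros(1))
        # token index = 1 + x + y*3 (+ z*6); x advances fastest
        assert seq.tokens[1, 0] == grid[0, 0, 0, 0]
        assert seq.tokens[2, 0] == grid[0, 1, 0, 0]
        assert seq.tokens[4, 0] == grid[0, 0, 1, 0]

    def test_scatter_back_inverts_raster(self, rng):
        grid = rng.normal(size=(6, 4, 3, 2))
        seq = tokenize(grid, np.zeros(6))
        np.testing.assert_array_equal(scatter_back(seq, (4, 3, 2)), grid)

    def test_positional_encoding_shape_checked(self, rng):
        with pytest.raises(ValueError):
            tokenize(rng.normal(size=(4, 2, 2, 1)), np.zeros(4),
                     positional_encodings=np.zeros((3, 4)))


class TestClassifier:
    @pytest.fixture(scope="class")
    def clf(self):
        return FusionClassifier(TINY_FUSION_CONFIG, (4, 4, 4), seed=3)

    def test_probabilities_sum_to_one(self, clf, rng):
        p = clf.predict_proba(rng.normal(size=(16, 4, 4, 4)),
                              rng.normal(size=(16, 4, 4, 4)))
        assert p.shape == (3,)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_tied_streams_give_identical_class_tokens(self, rng):
        cfg = TINY_FUSION_CONFIG
        clf = FusionClassifier(cfg, (4, 4, 4), seed=3)
        clf.adc_stream.load_state_dict(clf.t2_stream.state_dict())
        grid = rng.normal(size=(1, 4, 4, 4, 16)).astype(np.float32)
        a = clf._tokens(clf.t2_stream, Tensor(grid))
        b = clf._tokens(clf.adc_stream, Tensor(grid))
        for la, lb, fa, fb in zip(clf.t2_stream.layers, clf.adc_stream.layers,
                                  clf.t2_stream.fusers, clf.adc_stream.fusers):
            a, b = la(a), lb(b)
            na = fa(a[:, 0:1, :], b[:, 1:, :])
            nb = fb(b[:, 0:1, :], a[:, 1:, :])
            np.testing.assert_allclose(na.data, nb.data, atol=1e-6)
            from vqfusion.nn import concatenate
            a = concatenate([na, a[:, 1:, :]], axis=1)
            b = concatenate([nb, b[:, 1:, :]], axis=1)

    def test_positional_encodings_break_permutation_symmetry(self, rng):
        layer = TransformerLayer(TINY_FUSION_CONFIG, rng)
        x = rng.normal(size=(1, 6, 16))
        pe = rng.normal(size=(6, 16))
        perm = np.array([0, 3, 1, 5, 2, 4])
        out = layer(Tensor(x + pe)).data
        out_perm = layer(Tensor(x[:, perm] + pe)).data
        assert np.abs(out[:, perm] - out_perm).max() > 1e-4

    def test_sub_threshold_perturbation_keeps_logits_bit_identical(
        self, tiny_stage1, tiny_cases, clf
    ):
        """Corruption too small to flip any code assignment cannot change
        the prediction — the discreteness robustness mechanism."""
        case = tiny_cases[0]
        zt = quantised_grid(case.t2, tiny_stage1["t2"])
        za = quantised_grid(case.adc, tiny_stage1["adc"])
        bumped = case.t2.with_data(
            np.clip(case.t2.data + 1e-7 * np.sin(np.arange(case.t2.data.size))
                    .reshape(case.t2.shape), 0, 1)
        )
        zt2 = quantised_grid(bumped, tiny_stage1["t2"])
        q_before = quantise(encode(case.t2, tiny_stage1["t2"].encoder),
                            tiny_stage1["t2"].codebook)
        q_after = quantise(encode(bumped, tiny_stage1["t2"].encoder),
                           tiny_stage1["t2"].codebook)
        assert np.array_equal(q_before.indices, q_after.indices)
        p1 = clf.predict_proba(zt, za)
        p2 = clf.predict_proba(zt2, za)
        np.testing.assert_array_equal(p1, p2)


class TestTrainStage2:
    def _separable_grids(self, rng, n_per_class=6, shape=(4, 4, 4), d=16):
        out = []
        for label in range(3):
            for _ in range(n_per_class):
                base = np.zeros((d,) + shape)
                base += (label - 1) * 0.5
                base += rng.normal(0, 0.05, size=base.shape)
                out.append((base, base.copy(), label))
        return out

    def test_initial_loss_near_uniform_cross_entropy(self, rng):
        """On label-uninformative inputs the untrained classifier scores
        close to the uniform-prediction cross-entropy ln 3 (the
        variance-preserving init leaves a small non-uniform residual)."""
        data = [
            (g := rng.normal(0, 0.1, size=(16, 4, 4, 4)), g.copy(), label)
            for label in (0, 1, 2) for _ in range(6)
        ]
        clf = FusionClassifier(TINY_FUSION_CONFIG, (4, 4, 4), seed=0)
        hist = train_stage2(data, clf, TINY_FUSION_CONFIG, seed=0, max_steps=1)
        assert hist[0]["loss"] == pytest.approx(np.log(3), abs=0.25)

    def test_learns_separable_classes(self, rng):
        data = self._separable_grids(rng)
        cfg = replace(TINY_FUSION_CONFIG, lr=3e-3)
        clf = FusionClassifier(cfg, (4, 4, 4), seed=1)
        hist = train_stage2(data, clf, cfg, seed=1, max_steps=120)
        assert hist[-1]["train_accuracy"] >= 0.9

    def test_empty_dataset_rejected(self):
        clf = FusionClassifier(TINY_FUSION_CONFIG, (4, 4, 4), seed=0)
        with pytest.raises(ValueError):
            train_stage2([], clf, TINY_FUSION_CONFIG, seed=0)


def test_classify_end_to_end_contract(tiny_stage1, tiny_cases):
    clf = FusionClassifier(TINY_FUSION_CONFIG, (4, 4, 4), seed=9)
    p = classify(tiny_cases[0].t2, tiny_cases[0].adc, tiny_stage1, clf)
    assert p.shape == (3,) and p.sum() == pytest.approx(1.0, abs=1e-6)


def test_fusion_config_validation():
    with pytest.raises(ValueError):
        FusionConfig(d=30, n_heads=4)
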