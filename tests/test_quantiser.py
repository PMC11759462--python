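"""Codebook initialisation, nearest-code assignment, straight-through
gradients and the three-term VQ objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vqfusion.nn import Parameter, Tensor
from vqfusion.quantiser import (
    Codebook, LatentGrid, codebook_usage, init_codebook, load_codebook,
    nearest_code, quantise, save_codebook, straight_through, vq_loss_tensor,
    vq_losses,
)


def brute_force_nearest(vector, codes):
    """Independent oracle: explicit distance loop, first minimum wins."""
    best, best_d = 0, np.inf
    for j, row in enumerate(codes):
        d = np.sqrt(np.sum((np.asarray(vector) - row) ** 2))
        if d < best_d:
            best, best_d = j, d
    return best


class TestInitCodebook:
    def test_entries_within_uniform_bounds(self):
        cb = init_codebook(128, 256, seed=0)
        assert cb.codes.shape == (128, 256)
        assert cb.codes.min() >= -1 / 128 and cb.codes.max() <= 1 / 128

    def test_single_entry_boundary_case(self):
        cb = init_codebook(1, 1, seed=42)
        assert cb.codes.shape == (1, 1)
        assert -1.0 <= cb.codes[0, 0] <= 1.0

    def test_seed_determinism(self):
        a, b = init_codebook(4, 2, seed=7), init_codebook(4, 2, seed=7)
        np.testing.assert_array_equal(a.codes, b.codes)

    @pytest.mark.parametrize("K,d", [(0, 4), (4, 0), (-1, 2)])
    def test_nonpositive_dimensions_rejected(self, K, d):
        with pytest.raises(ValueError):
            init_codebook(K, d, seed=0)


class TestNearestCode:
    def test_exact_row_maps_to_itself(self):
        cb = init_codebook(8, 3, seed=1)
        assert nearest_code(cb.codes[3], cb) == 3

    def test_hand_computed_two_row_case(self):
        cb = Codebook(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert nearest_code(np.array([0.9, 0.9]), cb) == 1

    def test_matches_brute_force_oracle(self, rng):
        codes = rng.normal(size=(50, 8))
        cb = Codebook(codes)
        for _ in range(100):
            v = rng.normal(size=8)
            assert nearest_code(v, cb) == brute_force_nearest(v, codes)

    def test_tie_resolves_to_lowest_index(self):
        cb = Codebook(np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0]]))
        assert nearest_code(np.array([0.0, 0.0]), cb) == 0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nearest_code(np.zeros(3), init_codebook(4, 2, seed=0))


class TestQuantise:
    def test_codebook_rows_are_fixed_points(self, rng):
        cb = init_codebook(6, 4, seed=3)
        idx = rng.integers(0, 6, size=(2, 3, 2))
        grid = LatentGrid(cb.codes[idx].transpose(3, 0, 1, 2))
        q = quantise(grid, cb)
        np.testing.assert_array_equal(q.values, grid.values)
        np.testing.assert_array_equal(q.indices, idx)

    def test_single_site_equals_nearest_code(self, rng):
        cb = init_codebook(5, 4, seed=2)
        v = rng.normal(size=4)
        q = quantise(LatentGrid(v.reshape(4, 1, 1, 1)), cb)
        assert q.indices[0, 0, 0] == nearest_code(v, cb)

    def test_sitewise_agreement_with_oracle(self, rng):
        cb = init_codebook(16, 6, seed=4)
        grid = LatentGrid(rng.normal(size=(6, 4, 4, 3)))
        q = quantise(grid, cb)
        for x in range(4):
            for y in range(4):
                for z in range(3):
                    expected = brute_force_nearest(grid.values[:, x, y, z], cb.codes)
                    assert q.indices[x, y, z] == expected
                    np.testing.assert_array_equal(
                        q.values[:, x, y, z], cb.codes[expected]
                    )

    def test_idempotence(self, rng):
        cb = init_codebook(12, 5, seed=9)
        q1 = quantise(LatentGrid(rng.normal(size=(5, 3, 2, 2))), cb)
        q2 = quantise(LatentGrid(q1.values), cb)
        np.testing.assert_array_equal(q1.values, q2.values)
        np.testing.assert_array_equal(q1.indices, q2.indices)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            quantise(LatentGrid(rng.normal(size=(3, 2, 2, 2))),
                     init_codebook(4, 5, seed=0))


class TestStraightThrough:
    def test_forward_equals_quantised_values(self, rng):
        lat = Tensor(rng.normal(size=(4, 2, 2, 2)))
        q = rng.normal(size=(4, 2, 2, 2))
        np.testing.assert_array_equal(straight_through(lat, q).data, q)

    def test_sum_gradient_is_all_ones(self, rng):
        lat = Tensor(rng.normal(size=(3, 2, 2, 1)), requires_grad=True)
        straight_through(lat, rng.normal(size=(3, 2, 2, 1))).sum().backward()
        np.testing.assert_array_equal(lat.grad, np.ones_like(lat.data))

    def test_sum_of_squares_gradient_copies_decoder_input_gradient(self, rng):
        lat = Tensor(rng.normal(size=(4, 3, 2, 2)), requires_grad=True)
        q = rng.normal(size=(4, 3, 2, 2))
        (straight_through(lat, q) ** 2).sum().backward()
        np.testing.assert_allclose(lat.grad, 2.0 * q, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            straight_through(Tensor(np.zeros((2, 1, 1, 1))), np.zeros((3, 1, 1, 1)))


class TestVqLosses:
    def test_all_terms_zero_at_fixed_point(self, rng):
        cb = init_codebook(4, 3, seed=1)
        idx = rng.integers(0, 4, size=(2, 2, 1))
        values = cb.codes[idx].transpose(3, 0, 1, 2)
        vol = rng.random(size=(4, 4, 2))
        terms = vq_losses(vol, vol, LatentGrid(values),
                          quantise(LatentGrid(values), cb))
        assert terms.reconstruction == 0.0
        assert terms.codebook_term == 0.0
        assert terms.commitment_term == 0.0
        assert terms.total == 0.0

    def test_hand_computed_single_site_case(self):
        cb = Codebook(np.zeros((1, 2)))
        lat = LatentGrid(np.array([0.3, 0.4]).reshape(2, 1, 1, 1))
        q = quantise(lat, cb)
        vol = np.zeros((2, 2, 1))
        terms = vq_losses(vol, vol, lat, q, beta=0.25)
        assert terms.codebook_term == pytest.approx(0.5)
        assert terms.beta * terms.commitment_term == pytest.approx(0.125)

    def test_negative_beta_rejected(self, rng):
        cb = init_codebook(2, 2, seed=0)
        lat = LatentGrid(rng.normal(size=(2, 1, 1, 1)))
        with pytest.raises(ValueError):
            vq_losses(np.zeros((2, 2, 1)), np.zeros((2, 2, 1)), lat,
                      quantise(lat, cb), beta=-0.1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_total_is_weighted_sum(self, seed):
        r = np.random.default_rng(seed)
        cb = Codebook(r.normal(size=(5, 3)))
        lat = LatentGrid(r.normal(size=(3, 2, 2, 2)))
        recon, target = r.random((4, 4, 2)), r.random((4, 4, 2))
        terms = vq_losses(recon, target, lat, quantise(lat, cb), beta=0.25)
        assert terms.total == pytest.approx(
            terms.reconstruction + terms.codebook_term + 0.25 * terms.commitment_term,
            abs=1e-6,
        )
        assert min(terms.reconstruction, terms.codebook_term,
                   terms.commitment_term) >= 0.0

    def test_stop_gradient_separation(self, rng):
        """Codebook rows learn only via the codebook term, the encoder only
        via the commitment term."""
        cb_param = Parameter(rng.normal(size=(4, 3)))
        lat = Tensor(rng.normal(size=(3, 2, 2, 1)), requires_grad=True)
        q = quantise(LatentGrid(lat.data), Codebook(cb_param.data))
        recon = Tensor(rng.random((4, 4, 2)), requires_grad=True)
        total, terms = vq_loss_tensor(
            recon, recon.data.copy(), lat, cb_param, q.indices, beta=0.25
        )
        total.backward()
        full_cb, full_lat = cb_param.grad.copy(), lat.grad.copy()
        assert np.any(full_cb != 0) and np.any(full_lat != 0)

        # gradients through each term in isolation
        for p in (cb_param, lat):
            p.grad = None
        _, _ = 0, 0
        t2, _ = vq_loss_tensor(recon, recon.data.copy(), lat, cb_param,
                               q.indices, beta=0.0)
        t2.backward()
        cb_only = cb_param.grad.copy()
        np.testing.assert_allclose(cb_only, full_cb, atol=1e-12)
        # with beta=0 the latent receives no commitment gradient
        assert lat.grad is None or np.allclose(lat.grad, 0.0)


def test_codebook_usage_histogram():
    idx = np.array([[0, 1], [1, 3]])
    np.testing.assert_array_equal(codebook_usage(idx, 5), [1, 2, 0, 1, 0])


def test_codebook_checkpoint_roundtrip(tmp_path):
    cb = init_codebook(6, 4, seed=77)
    path = tmp_path / "codebook.txt"
    save_codebook(cb, path)
    back = load_codebook(path)
    np.testing.assert_allclose(back.codes, cb.codes, atol=1e-12)
    assert (back.K, back.d, back.seed) == (6, 4, 77)
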