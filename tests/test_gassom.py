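"""Subspace coding: patch extraction, responses, errors, online updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aecvision import gassom

from conftest import random_orthonormal_basis


def brute_force_response(basis, x):
    """Oracle: r = c1^2 + c2^2 with c_i the inner products with the columns."""
    c1 = float(basis[:, 0] @ x)
    c2 = float(basis[:, 1] @ x)
    return c1 * c1 + c2 * c2


class TestPatchify:
    def test_55x55_stride5_yields_100_patches(self, rng):
        left = rng.random((55, 55))
        right = rng.random((55, 55))
        x, active, grid = gassom.patchify(left, right, stride=5)
        assert x.shape == (100, 200)
        assert grid == (10, 10)

    def test_constant_window_gives_zero_vectors_flagged(self):
        left = np.full((25, 25), 0.5)
        x, active, _ = gassom.patchify(left, left, stride=5)
        np.testing.assert_array_equal(x, 0.0)
        assert not active.any()

    def test_halves_normalized_to_zero_mean_unit_variance(self, rng):
        left = rng.random((25, 25))
        right = rng.random((25, 25))
        x, active, _ = gassom.patchify(left, right, stride=5)
        assert active.all()
        for half in (x[:, :100], x[:, 100:]):
            np.testing.assert_allclose(half.mean(axis=1), 0.0, atol=1e-9)
            np.testing.assert_allclose(half.var(axis=1), 1.0, atol=1e-9)

    def test_patch_content_matches_naive_crop(self, rng):
        left = rng.random((25, 25))
        right = rng.random((25, 25))
        x, _, grid = gassom.patchify(left, right, stride=5)
        i, j = 2, 3  # grid position
        raw = left[10:20, 15:25].ravel()
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(x[i * grid[1] + j, :100], expected, atol=1e-12)

    def test_window_smaller_than_patch_rejected(self):
        with pytest.raises(ValueError):
            gassom.patchify(np.zeros((5, 5)), np.zeros((5, 5)), stride=1)


class TestResponses:
    def test_basis_column_has_unit_response(self, small_bank):
        x = small_bank.bases[3, :, 0]
        r = gassom.subspace_responses(small_bank, x)[0]
        assert np.isclose(r[3], 1.0)

    def test_orthogonal_vector_has_zero_response(self, rng, small_bank):
        basis = small_bank.bases[0]
        x = rng.standard_normal(30)
        x -= basis @ (basis.T @ x)  # project out
        assert np.isclose(gassom.subspace_responses(small_bank, x)[0, 0], 0.0, atol=1e-12)

    def test_matches_dot_product_oracle(self, rng, small_bank):
        for _ in range(100):
            x = rng.standard_normal(30)
            r = gassom.subspace_responses(small_bank, x)[0]
            n = rng.integers(20)
            assert np.isclose(r[n], brute_force_response(small_bank.bases[n], x), atol=1e-10)

    def test_energy_bound(self, rng, small_bank):
        x = rng.standard_normal((50, 30))
        r = gassom.subspace_responses(small_bank, x)
        energy = (x**2).sum(axis=1)
        assert np.all(r >= 0)
        assert np.all(r <= energy[:, None] + 1e-9)


class TestBestSubspace:
    def test_exact_member_has_zero_error(self, rng, small_bank):
        basis = small_bank.bases[7]
        x = basis @ rng.standard_normal(2)
        m, e = gassom.best_subspace_and_error(small_bank, x)
        assert m[0] == 7
        assert e[0] < 1e-12

    def test_pythagoras_identity(self, rng, small_bank):
        x = rng.standard_normal((40, 30))
        r = gassom.subspace_responses(small_bank, x)
        m, e = gassom.best_subspace_and_error(small_bank, x)
        energy = (x**2).sum(axis=1)
        np.testing.assert_allclose(e + r[np.arange(40), m], energy, atol=1e-9)

    def test_matches_exhaustive_scan(self, rng, small_bank):
        for _ in range(100):
            x = rng.standard_normal(30)
            m, e = gassom.best_subspace_and_error(small_bank, x)
            rs = [brute_force_response(small_bank.bases[n], x) for n in range(20)]
            assert m[0] == int(np.argmax(rs))
            assert np.isclose(e[0], x @ x - max(rs), atol=1e-10)


class TestScaleError:
    def test_perfectly_representable_patches_give_zero(self, rng, small_bank):
        coeffs = rng.standard_normal((10, 2))
        x = coeffs @ small_bank.bases[4].T
        assert gassom.scale_error(small_bank, x) < 1e-12

    def test_average_error_of_equal_scales(self):
        assert gassom.average_error(0.3, 0.3, 0.3) == pytest.approx(0.3)

    def test_matches_naive_loop(self, rng, small_bank):
        x = rng.standard_normal((15, 30))
        total = 0.0
        for xi in x:
            rs = [brute_force_response(small_bank.bases[n], xi) for n in range(20)]
            total += xi @ xi - max(rs)
        assert np.isclose(gassom.scale_error(small_bank, x), total / 15, atol=1e-10)

    def test_empty_patch_list_rejected(self, small_bank):
        with pytest.raises(ValueError):
            gassom.scale_error(small_bank, np.empty((0, 30)))


class TestResponsibilities:
    def test_equal_responses_no_history_is_uniform(self, small_bank):
        r = np.full((1, 20), 0.4)
        h = gassom.responsibilities(small_bank, r, None)
        np.testing.assert_allclose(h, 1 / 20)

    def test_rows_sum_to_one_and_nonnegative(self, rng, small_bank):
        r = rng.random((30, 20)) * 5
        h = gassom.responsibilities(small_bank, r, rng.integers(0, 20, 30))
        assert np.all(h >= 0)
        np.testing.assert_allclose(h.sum(axis=1), 1.0, atol=1e-12)

    def test_small_sigma_approaches_one_hot(self, small_bank):
        bank = gassom.SubspaceBank(small_bank.bases, sigma_e=0.01)
        r = np.array([[0.1, 0.9] + [0.2] * 18])
        h = gassom.responsibilities(bank, r, None)
        assert h[0, 1] > 0.999

    def test_matches_documented_formula(self, rng, small_bank):
        r = rng.random((5, 20)) * 3
        prev = rng.integers(0, 20, 5)
        h = gassom.responsibilities(small_bank, r, prev)
        for p in range(5):
            prior = np.full(20, (1 - small_bank.omega) / 19)
            prior[prev[p]] = small_bank.omega
            raw = np.exp(r[p] / (2 * small_bank.sigma_e**2)) * prior
            np.testing.assert_allclose(h[p], raw / raw.sum(), atol=1e-10)

    def test_hard_assignment_mode(self, small_bank):
        bank = gassom.SubspaceBank(small_bank.bases, hard_assign=True)
        r = np.array([[0.3, 0.8, 0.1] + [0.0] * 17])
        h = gassom.responsibilities(bank, r, None)
        assert h[0, 1] == 1.0 and h.sum() == 1.0


class TestUpdateBank:
    def test_in_subspace_patches_with_one_hot_h_leave_bank_unchanged(self, rng, small_bank):
        # every patch lies exactly in the subspace it is assigned to
        x = np.stack([small_bank.bases[n] @ rng.standard_normal(2) for n in range(5)])
        h = np.zeros((5, 20))
        h[np.arange(5), np.arange(5)] = 1.0
        before = small_bank.bases.copy()
        gassom.update_bank(small_bank, x, h, lr=0.05)
        np.testing.assert_allclose(small_bank.bases, before, atol=1e-12)

    def test_single_patch_residual_strictly_decreases(self, rng, small_bank):
        x = rng.standard_normal(30)
        m, e0 = gassom.best_subspace_and_error(small_bank, x)
        h = np.zeros((1, 20))
        h[0, m[0]] = 1.0
        gassom.update_bank(small_bank, x[None], h, lr=0.01)
        _, e1 = gassom.best_subspace_and_error(small_bank, x)
        assert e1[0] < e0[0]

    def test_orthonormality_preserved_after_updates(self, rng, small_bank):
        for _ in range(10):
            x = rng.standard_normal((8, 30))
            h = gassom.responsibilities(
                small_bank, gassom.subspace_responses(small_bank, x), None
            )
            gassom.update_bank(small_bank, x, h, lr=0.05)
        gram = np.einsum("nde,ndf->nef", small_bank.bases, small_bank.bases)
        np.testing.assert_allclose(gram, np.broadcast_to(np.eye(2), (20, 2, 2)), atol=1e-8)

    def test_zero_norm_patch_contributes_nothing(self, small_bank):
        x = np.zeros((1, 30))
        h = np.full((1, 20), 1 / 20)
        before = small_bank.bases.copy()
        gassom.update_bank(small_bank, x, h, lr=0.1)
        np.testing.assert_allclose(small_bank.bases, before, atol=1e-12)

    def test_nonpositive_learning_rate_rejected(self, small_bank):
        with pytest.raises(ValueError):
            gassom.update_bank(small_bank, np.ones((1, 30)), np.ones((1, 20)), lr=0.0)


class TestInitBank:
    def test_deterministic_per_seed(self):
        a = gassom.init_bank(10, seed=3, dim=50)
        b = gassom.init_bank(10, seed=3, dim=50)
        np.testing.assert_array_equal(a.bases, b.bases)

    def test_all_pairs_orthonormal(self):
        bank = gassom.init_bank(324, seed=0)
        gram = np.einsum("nde,ndf->nef", bank.bases, bank.bases)
        np.testing.assert_allclose(gram, np.broadcast_to(np.eye(2), (324, 2, 2)), atol=1e-10)

    def test_full_scale_bank_has_324_subspaces_of_dim_200(self):
        bank = gassom.init_bank(324, seed=1)
        assert bank.bases.shape == (324, 200, 2)


class TestLearning:
    def test_planted_subspace_recovery(self, rng):
        """Training on data from 20 planted 2-D subspaces cuts error >= 80%."""
        dim = 30
        planted = [random_orthonormal_basis(rng, dim) for _ in range(20)]
        bank = gassom.init_bank(20, seed=11, dim=dim)

        def batch(n):
            idx = rng.integers(0, 20, n)
            coeffs = rng.standard_normal((n, 2))
            x = np.stack([planted[i] @ c for i, c in zip(idx, coeffs)])
            return x / np.linalg.norm(x, axis=1, keepdims=True)

        test = batch(400)
        e0 = gassom.scale_error(bank, test)
        n_iter = 3000
        for t in range(n_iter):
            bank.reset_stream()  # batches are i.i.d.: no temporal continuity
            x = batch(10)
            bank.adapt(x, np.ones(len(x), dtype=bool), lr=0.2 * (1 - 0.9 * t / n_iter))
        e1 = gassom.scale_error(bank, test)
        assert e1 <= 0.2 * e0

    def test_bit_identical_trajectory_for_same_seed_and_stream(self, rng):
        data = rng.standard_normal((20, 8, 30))
        results = []
        for _ in range(2):
            bank = gassom.init_bank(12, seed=5, dim=30)
            for x in data:
                bank.adapt(x, np.ones(8, dtype=bool), lr=0.05)
            results.append(bank.bases.copy())
        np.testing.assert_array_equal(results[0], results[1])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_response_energy_bound_property(seed):
    """0 <= r_n(x) <= ||x||^2 and e = ||x||^2 - max r_n for random inputs."""
    rng = np.random.default_rng(seed)
    bank = gassom.init_bank(8, seed=seed % 1000, dim=20)
    x = rng.standard_normal((5, 20))
    r = gassom.subspace_responses(bank, x)
    energy = (x**2).sum(axis=1)
    assert np.all(r >= 0) and np.all(r <= energy[:, None] + 1e-9)
    _, e = gassom.best_subspace_and_error(bank, x)
    np.testing.assert_allclose(e, energy - r.max(axis=1), atol=1e-9)
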