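import itertools
from dataclasses import replace

import numpy as np
import pytest

from riemcell.patch_features import PatchGrid
from riemcell.riemannian_dictionary import (
    DictionaryModel,
    WeightField,
    dictionary_loss,
    encode_field,
    encode_weights,
    fit_dictionary,
    init_dictionary,
    load_model,
    reconstruct_spd,
    save_model,
)
from riemcell.riemannian_dictionary import _loss_and_grads, _neighbor_pairs, _tangent_vectors
from riemcell.spd_core import spd_log, stein_divergence, tangent_vectorize
from riemcell.synthetic_data import random_spd


def tiny_grid(rows, cols, p=4):
    origins = tuple((r * p, c * p) for r in range(rows) for c in range(cols))
    return PatchGrid(patch_size=p, stride=p, grid_dims=(rows, cols),
                     patch_origins=origins, image_shape=(rows * p, cols * p))


@pytest.fixture(scope="module")
def small_covs():
    return [random_spd(4, 30, s) for s in range(6)]


class TestInitDictionary:
    def test_k1_atom_is_mean_tangent(self, small_covs):
        model = init_dictionary(small_covs, K=1, seed=0)
        mean_vec = np.mean(
            [tangent_vectorize(spd_log(c)).values for c in small_covs], axis=0
        )
        assert np.allclose(tangent_vectorize(model.atoms[0]).values, mean_vec, atol=1e-8)

    def test_deterministic(self, small_covs):
        a = init_dictionary(small_covs, K=3, seed=4)
        b = init_dictionary(small_covs, K=3, seed=4)
        assert np.array_equal(a.atoms, b.atoms)
        assert np.array_equal(a.encoder_weights, b.encoder_weights)

    def test_atoms_symmetric(self, small_covs):
        model = init_dictionary(small_covs, K=3, seed=0)
        assert np.allclose(model.atoms, model.atoms.transpose(0, 2, 1))

    def test_k_too_large(self, small_covs):
        with pytest.raises(ValueError):
            init_dictionary(small_covs, K=10, seed=0)


class TestEncodeWeights:
    def test_constant_encoder(self, small_covs):
        d = 4
        p = d * (d + 1) // 2
        model = DictionaryModel(
            atoms=np.zeros((3, d, d)),
            encoder_weights=np.zeros((3, p)),
            encoder_bias=np.array([1.0, 0.0, 0.0]),
        )
        for c in small_covs:
            assert np.allclose(encode_weights(model, c), [1.0, 0.0, 0.0])

    def test_matches_bruteforce_matvec(self, small_covs):
        model = init_dictionary(small_covs, K=3, seed=0)
        A = small_covs[2]
        z = tangent_vectorize(spd_log(A)).values
        expected = [
            sum(model.encoder_weights[k, j] * z[j] for j in range(z.size))
            + model.encoder_bias[k]
            for k in range(3)
        ]
        assert np.allclose(encode_weights(model, A), expected, atol=1e-10)

    def test_affine_in_tangent_input(self, small_covs):
        from riemcell.spd_core import spd_exp, tangent_unvectorize

        model = init_dictionary(small_covs, K=3, seed=0)
        rng = np.random.default_rng(0)
        z1, z2 = rng.standard_normal((2, 10)) * 0.3
        A1 = spd_exp(tangent_unvectorize(z1))
        A2 = spd_exp(tangent_unvectorize(z2))
        A12 = spd_exp(tangent_unvectorize(z1 + z2))
        lhs = encode_weights(model, A12)
        rhs = encode_weights(model, A1) + encode_weights(model, A2) - model.encoder_bias
        assert np.allclose(lhs, rhs, atol=1e-8)


class TestReconstruct:
    def test_perfect_single_atom_code(self):
        A = random_spd(4, 20, 0)
        model = DictionaryModel(
            atoms=spd_log(A).values[None],
            encoder_weights=np.zeros((1, 10)),
            encoder_bias=np.zeros(1),
        )
        out = reconstruct_spd(model, [1.0])
        assert np.allclose(out.values, A.values, atol=1e-8)

    def test_zero_weights_give_identity(self, small_covs):
        model = init_dictionary(small_covs, K=3, seed=0)
        assert np.allclose(reconstruct_spd(model, np.zeros(3)).values, np.eye(4))

    def test_optimal_scalar_code_beats_identity(self):
        # line-search oracle over scalar ω for a single atom
        A = random_spd(3, 40, 5)
        Z = spd_log(A).values
        model = DictionaryModel(
            atoms=Z[None], encoder_weights=np.zeros((1, 6)), encoder_bias=np.zeros(1)
        )
        best = min(
            stein_divergence(A, reconstruct_spd(model, [w]))
            for w in np.linspace(-1, 2, 301)
        )
        assert best <= stein_divergence(A.values, np.eye(3)) + 1e-12

    def test_output_always_spd_fuzz(self, small_covs):
        model = init_dictionary(small_covs, K=3, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = reconstruct_spd(model, rng.standard_normal(3))
            assert np.allclose(out.values, out.values.T)
            assert np.linalg.eigvalsh(out.values).min() > 0


class TestDictionaryLoss:
    def test_perfect_reconstruction_zero_loss(self):
        A = random_spd(3, 10, 1)
        model = DictionaryModel(
            atoms=spd_log(A).values[None],
            encoder_weights=np.zeros((1, 6)),
            encoder_bias=np.ones(1),
            alpha=0.0,
            beta=0.0,
        )
        grid = tiny_grid(1, 4)
        field = encode_field(model, [A] * 4, grid)
        total, parts = dictionary_loss(model, [A] * 4, field)
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_constant_field_zero_smoothness(self, small_covs):
        model = init_dictionary(small_covs, K=2, seed=0, beta=0.5)
        grid = tiny_grid(2, 3)
        field = WeightField(weights=np.ones((2, 3, 2)), grid=grid)
        _, parts = dictionary_loss(model, small_covs, field)
        assert parts["smooth"] == 0.0

    def test_parts_match_bruteforce_oracle(self, small_covs):
        model = init_dictionary(small_covs, K=2, seed=1, alpha=0.3, beta=0.7)
        grid = tiny_grid(2, 3)
        rng = np.random.default_rng(0)
        W = rng.standard_normal((2, 3, 2))
        field = WeightField(weights=W, grid=grid)
        total, parts = dictionary_loss(model, small_covs, field)
        # naive double-loop oracle
        flat = W.reshape(6, 2)
        stein = np.mean(
            [
                stein_divergence(
                    small_covs[i],
                    reconstruct_spd(model, flat[i]),
                )
                for i in range(6)
            ]
        )
        l1 = 0.3 * np.mean([np.abs(flat[i]).sum() for i in range(6)])
        pair_sq, n_pairs = 0.0, 0
        for (r1, c1), (r2, c2) in itertools.combinations(
            itertools.product(range(2), range(3)), 2
        ):
            if abs(r1 - r2) + abs(c1 - c2) == 1:
                pair_sq += ((W[r1, c1] - W[r2, c2]) ** 2).sum()
                n_pairs += 1
        smooth = 0.7 * pair_sq / n_pairs
        assert parts["stein"] == pytest.approx(stein, abs=1e-10)
        assert parts["l1"] == pytest.approx(l1, abs=1e-10)
        assert parts["smooth"] == pytest.approx(smooth, abs=1e-10)
        assert total == pytest.approx(stein + l1 + smooth, abs=1e-10)


class TestGradients:
    def test_stein_gradients_match_finite_differences(self, small_covs):
        model = init_dictionary(small_covs, K=3, seed=0, alpha=0.0, beta=0.0)
        A = np.stack([c.values for c in small_covs])
        Z = _tangent_vectors(small_covs)
        pairs = _neighbor_pairs(2, 3)
        _, _, dW, db, dA = _loss_and_grads(model, A, Z, pairs)

        def loss_of(m):
            return _loss_and_grads(m, A, Z, pairs)[0]

        eps = 1e-6
        # encoder weights: relative error of the full gradient vector
        fd_W = np.zeros_like(dW)
        for i, j in itertools.product(range(3), range(10)):
            Wp, Wm = model.encoder_weights.copy(), model.encoder_weights.copy()
            Wp[i, j] += eps
            Wm[i, j] -= eps
            fd_W[i, j] = (
                loss_of(replace(model, encoder_weights=Wp))
                - loss_of(replace(model, encoder_weights=Wm))
            ) / (2 * eps)
        assert np.linalg.norm(fd_W - dW) / np.linalg.norm(fd_W) < 1e-4
        # atoms: symmetric perturbations
        fd_A = []
        anal_A = []
        for k, a, b in itertools.product(range(3), range(4), range(4)):
            if a > b:
                continue
            Ap, Am = model.atoms.copy(), model.atoms.copy()
            if a == b:
                Ap[k, a, a] += eps
                Am[k, a, a] -= eps
                anal_A.append(dA[k, a, a])
            else:
                Ap[k, a, b] += eps
                Ap[k, b, a] += eps
                Am[k, a, b] -= eps
                Am[k, b, a] -= eps
                anal_A.append(dA[k, a, b] + dA[k, b, a])
            fd_A.append(
                (loss_of(replace(model, atoms=Ap)) - loss_of(replace(model, atoms=Am)))
                / (2 * eps)
            )
        fd_A, anal_A = np.array(fd_A), np.array(anal_A)
        assert np.linalg.norm(fd_A - anal_A) / np.linalg.norm(fd_A) < 1e-4


class TestFitDictionary:
    def test_single_point_fit_converges(self):
        A = random_spd(4, 50, 1)
        covs = [A] * 8
        grid = tiny_grid(2, 4)
        model = init_dictionary(covs, K=1, seed=0, alpha=0.0, beta=0.0)
        model, hist = fit_dictionary(model, covs, grid, epochs=200, lr=1e-2)
        field = encode_field(model, covs, grid)
        _, parts = dictionary_loss(model, covs, field)
        assert parts["stein"] < 1e-4

    def test_history_length(self, small_covs):
        model = init_dictionary(small_covs, K=2, seed=0)
        _, hist = fit_dictionary(model, small_covs, tiny_grid(2, 3), epochs=7, lr=1e-2)
        assert len(hist) == 7

    def test_improves_on_scene(self, scene_descriptors):
        _, grid, covs = scene_descriptors
        model = init_dictionary(covs, K=4, seed=0)
        field = encode_field(model, covs, grid)
        initial, _ = dictionary_loss(model, covs, field)
        fitted, hist = fit_dictionary(model, covs, grid, epochs=40, lr=1e-2)
        field = encode_field(fitted, covs, grid)
        final, _ = dictionary_loss(fitted, covs, field)
        assert final < initial
        assert hist[0] == pytest.approx(initial, rel=1e-9)

    def test_deterministic(self, small_covs):
        grid = tiny_grid(2, 3)
        m0 = init_dictionary(small_covs, K=2, seed=0)
        a, ha = fit_dictionary(m0, small_covs, grid, epochs=10, lr=1e-2)
        b, hb = fit_dictionary(m0, small_covs, grid, epochs=10, lr=1e-2)
        assert ha == hb
        assert np.array_equal(a.atoms, b.atoms)

    def test_preconditions(self, small_covs):
        model = init_dictionary(small_covs, K=2, seed=0)
        with pytest.raises(ValueError):
            fit_dictionary(model, small_covs, tiny_grid(2, 3), epochs=0, lr=1e-2)
        with pytest.raises(ValueError):
            fit_dictionary(model, small_covs, tiny_grid(2, 3), epochs=1, lr=0.0)


def test_save_load_roundtrip(tmp_path, small_covs):
    model = init_dictionary(small_covs, K=3, seed=0)
    save_model(model, str(tmp_path / "dict"))
    back = load_model(str(tmp_path / "dict"))
    assert np.array_equal(back.atoms, model.atoms)
    assert np.array_equal(back.encoder_weights, model.encoder_weights)
    assert back.alpha == model.alpha
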