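import numpy as np
import pytest

from riemcell.latent_embedding import (
    CellCrop,
    EncoderConfig,
    LatentVector,
    cluster_area_stats,
    cluster_embeddings,
    crop_cells,
    embed_cells,
    reconstruct,
    train_autoencoder,
    tsne_project,
)
from riemcell.synthetic_data import generate_cell_crops

TINY = dict(feature_depth=32, latent_dim=16, batch=8, epochs=2)


@pytest.fixture(scope="module")
def tiny_crops():
    return [s.crop for s in generate_cell_crops(16, [0.5, 0.5], seed=0)]


@pytest.fixture(scope="module")
def tiny_model(tiny_crops):
    return train_autoencoder(tiny_crops, EncoderConfig(seed=0, **TINY))


class TestCropCells:
    def test_single_square_instance(self):
        img = np.zeros((100, 100))
        lab = np.zeros((100, 100), dtype=np.int32)
        img[30:70, 30:70] = 0.8
        lab[30:70, 30:70] = 1
        crops = crop_cells(img, lab)
        assert len(crops) == 1
        c = crops[0]
        assert c.orig_size == (40, 40)
        assert c.orig_area == 1600
        assert c.bbox == (30, 70, 30, 70)
        # mask true on the scaled square only, which fills the whole canvas
        assert c.padding_mask.all()

    def test_two_instances_ascending_order(self):
        img = np.ones((60, 60)) * 0.5
        lab = np.zeros((60, 60), dtype=np.int32)
        lab[5:15, 5:15] = 2
        lab[30:55, 30:45] = 1
        crops = crop_cells(img, lab)
        assert len(crops) == 2
        assert crops[0].bbox == (30, 55, 30, 45)  # label 1 first
        assert crops[1].bbox == (5, 15, 5, 15)

    def test_letterbox_for_nonsquare(self):
        img = np.ones((60, 60))
        lab = np.zeros((60, 60), dtype=np.int32)
        lab[10:20, 10:50] = 1  # 10×40 → scales to 32×128
        c = crop_cells(img, lab)[0]
        assert c.padding_mask[:40].sum() == 0  # top letterbox empty
        assert np.allclose(c.pixels[~c.padding_mask], -1.0)

    def test_masked_background_zeroed(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        lab = np.zeros((64, 64), dtype=np.int32)
        lab[20:40, 20:40] = 1
        c = crop_cells(img, lab)[0]
        assert np.allclose(c.pixels[~c.padding_mask], -1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            crop_cells(np.zeros((4, 4)), np.zeros((5, 5), dtype=np.int32))


class TestTrainAutoencoder:
    def test_loss_history_and_determinism(self, tiny_crops):
        cfg = EncoderConfig(seed=1, **TINY)
        _, h1 = train_autoencoder(tiny_crops, cfg)
        _, h2 = train_autoencoder(tiny_crops, EncoderConfig(seed=1, **TINY))
        assert len(h1) == 2
        assert h1 == h2

    def test_loss_decreases_on_longer_run(self):
        crops = [s.crop for s in generate_cell_crops(48, [0.5, 0.5], seed=2)]
        cfg = EncoderConfig(seed=0, feature_depth=32, latent_dim=16, batch=16,
                            epochs=5, lr=1e-3)
        _, hist = train_autoencoder(crops, cfg)
        assert len(hist) == 5
        assert hist[-1] < hist[0]

    def test_vae_kld_nonnegative(self, tiny_crops):
        cfg = EncoderConfig(seed=0, variant="VAE", **TINY)
        model, hist = train_autoencoder(tiny_crops, cfg)
        from riemcell.latent_embedding.model import _crop_arrays, _loss
        from riemcell.latent_embedding._autograd import Tensor

        px, masks, shapes = _crop_arrays(tiny_crops)
        rng = np.random.default_rng(0)
        recon, _, mu, logvar = model.forward(Tensor(px), shapes, masks, train=True, rng=rng)
        _, parts = _loss(recon, Tensor(px), mu, logvar, cfg)
        assert parts["kld"] >= 0.0

    def test_mhaae_variant_trains(self, tiny_crops):
        cfg = EncoderConfig(seed=0, variant="MHAAE", **TINY)
        model, hist = train_autoencoder(tiny_crops, cfg)
        assert len(hist) == 2 and np.isfinite(hist).all()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            EncoderConfig(variant="GAN")
        with pytest.raises(ValueError):
            EncoderConfig(loss_terms=("LPIPS",))

    def test_empty_crops_rejected(self):
        with pytest.raises(ValueError):
            train_autoencoder([], EncoderConfig(**TINY))


class TestEmbedCells:
    def test_unit_norm_and_dim(self, tiny_model, tiny_crops):
        model, _ = tiny_model
        latents = embed_cells(model, tiny_crops)
        assert len(latents) == len(tiny_crops)
        for v in latents:
            assert v.values.shape == (16,)
            assert np.linalg.norm(v.values) == pytest.approx(1.0, abs=1e-6)

    def test_identical_crops_identical_latents(self, tiny_model, tiny_crops):
        model, _ = tiny_model
        a = embed_cells(model, [tiny_crops[0], tiny_crops[0]])
        assert np.array_equal(a[0].values, a[1].values)

    def test_reconstruction_beats_mean_predictor(self):
        # MAE-only training: the SSIM term gains nothing on the unpredictable
        # in-cell speckle and steers the optimum toward flat background
        crops = [s.crop for s in generate_cell_crops(200, [0.5, 0.5], seed=3)]
        held = [s.crop for s in generate_cell_crops(48, [0.5, 0.5], seed=99)]
        cfg = EncoderConfig(feature_depth=64, latent_dim=32, batch=32, epochs=70,
                            lr=5e-3, lr_decay=0.99, seed=0, loss_terms=("MAE",))
        model, _ = train_autoencoder(crops, cfg)
        rec = reconstruct(model, held)
        target = np.stack([c.pixels for c in held])
        mean_img = np.mean([c.pixels for c in crops], axis=0)
        mae_model = np.abs(rec - target).mean()
        mae_mean = np.abs(mean_img[None] - target).mean()
        assert mae_model < mae_mean


class TestTsneProject:
    def test_orthogonal_bundles_separate(self):
        rng = np.random.default_rng(0)
        a = np.tile([1.0] + [0.0] * 15, (60, 1)) + 0.01 * rng.standard_normal((60, 16))
        b = np.tile([0.0, 1.0] + [0.0] * 14, (60, 1)) + 0.01 * rng.standard_normal((60, 16))
        X = np.vstack([a, b])
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        pts = tsne_project(X, perplexity=10, seed=0)
        from sklearn.metrics import silhouette_score

        labels = np.r_[np.zeros(60), np.ones(60)]
        assert silhouette_score(pts, labels) > 0.5

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 8))
        a = tsne_project(X, perplexity=5, seed=7)
        b = tsne_project(X, perplexity=5, seed=7)
        assert np.array_equal(a, b)

    def test_identical_inputs_complete(self):
        X = np.tile(np.ones(8) / np.sqrt(8), (40, 1))
        pts = tsne_project(X, perplexity=5, seed=0)
        assert pts.shape == (40, 2)
        assert np.allclose(pts.mean(axis=0), 0, atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            tsne_project(np.zeros((10, 4)), perplexity=10, seed=0)


class TestClusterEmbeddings:
    def test_two_blobs(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([
            rng.standard_normal((500, 2)) + [20, 0],
            rng.standard_normal((500, 2)) - [20, 0],
        ])
        truth = np.r_[np.zeros(500), np.ones(500)]
        res = cluster_embeddings(pts, 0.02)
        assert res.n_clusters == 2
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, res.labels) >= 0.95

    def test_min_cluster_size_rule(self):
        # frac 0.02 with n = 1000 → min cluster size 20
        rng = np.random.default_rng(1)
        pts = rng.random((1000, 2))
        res = cluster_embeddings(pts, 0.02)
        labels, counts = np.unique(res.labels[res.labels >= 0], return_counts=True)
        assert np.all(counts >= 20)
        assert set(res.labels.tolist()) <= set(range(-1, 1000))

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cluster_embeddings(np.zeros((5, 2)), 0.02)
        with pytest.raises(ValueError):
            cluster_embeddings(np.zeros((20, 2)), 1.5)


class TestClusterAreaStats:
    def _crop_with_area(self, area):
        mask = np.zeros((128, 128), dtype=bool)
        side = int(np.sqrt(area))
        mask[:side, : area // side] = True
        extra = area - mask.sum()
        if extra:
            mask[side, :extra] = True
        return CellCrop(
            pixels=np.zeros((128, 128)),
            padding_mask=mask,
            orig_size=(side + 1, max(area // side, extra)),
            orig_area=int(area),
            bbox=(0, side + 1, 0, max(area // side, extra, 1)),
        )

    def test_zero_variance(self):
        crops = [self._crop_with_area(100) for _ in range(3)]
        res = cluster_area_stats(np.zeros(3, dtype=int), crops)
        assert res.stats[0].n == 3
        assert res.stats[0].mean_area == 100
        assert res.stats[0].sem_area == 0.0

    def test_hand_computed_sem(self):
        crops = [self._crop_with_area(90), self._crop_with_area(110)]
        res = cluster_area_stats(np.zeros(2, dtype=int), crops)
        # sd = 14.142…, SEM = sd/√2 = 10
        assert res.stats[0].mean_area == pytest.approx(100.0)
        assert res.stats[0].sem_area == pytest.approx(10.0)

    def test_noise_excluded(self):
        crops = [self._crop_with_area(a) for a in (50, 60, 1000)]
        labels = np.array([0, 0, -1])
        res = cluster_area_stats(labels, crops)
        assert set(res.stats) == {0}
        assert res.stats[0].mean_area == pytest.approx(55.0)

    def test_equal_subsampling(self):
        crops = [self._crop_with_area(a) for a in range(50, 80)]
        labels = np.zeros(30, dtype=int)
        res = cluster_area_stats(labels, crops, subsample_size=10, seed=0)
        assert res.stats[0].n == 10


def test_latent_vector_rejects_non_unit():
    with pytest.raises(ValueError):
        LatentVector(np.ones(4))
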