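import numpy as np
import pytest

from riemcell.patch_features import extract_patches, feature_stack, patch_covariance_grid
from riemcell.synthetic_data import generate_texture_scene


@pytest.fixture(scope="session")
def two_class_scene():
    return generate_texture_scene(128, 128, 6, 2, seed=0)


@pytest.fixture(scope="session")
def scene_descriptors(two_class_scene):
    stack = feature_stack(two_class_scene.image)
    grid, _ = extract_patches(stack, 8, 4)
    covs = patch_covariance_grid(stack, grid, eps=1e-6)
    return stack, grid, covs


@pytest.fixture(scope="session")
def latent_pipeline_run():
    """The full latent-arm recovery run, shared by invariant + acceptance tests.

    600 synthetic crops of 2 shape classes, AE (default config) for 20 epochs,
    embedding, t-SNE, HDBSCAN at the 2% rule. Trains once per session (~6 min).
    """
    from riemcell.latent_embedding import (
        EncoderConfig,
        cluster_embeddings,
        embed_cells,
        train_autoencoder,
        tsne_project,
    )
    from riemcell.synthetic_data import generate_cell_crops

    samples = generate_cell_crops(600, [0.5, 0.5], seed=1)
    crops = [s.crop for s in samples]
    true_classes = np.array([s.true_class for s in samples])
    config = EncoderConfig(epochs=20, seed=0)
    model, history = train_autoencoder(crops, config)
    latents = embed_cells(model, crops)
    points = tsne_project(latents, perplexity=30.0, seed=0)
    clusters = cluster_embeddings(points, min_cluster_frac=0.02)
    return {
        "crops": crops,
        "true_classes": true_classes,
        "config": config,
        "model": model,
        "history": history,
        "latents": latents,
        "points": points,
        "clusters": clusters,
    }


def patch_majority_classes(label_map: np.ndarray, grid) -> np.ndarray:
    """Ground-truth patch class = majority label over the patch footprint."""
    p = grid.patch_size
    out = []
    for r, c in grid.patch_origins:
        vals, counts = np.unique(label_map[r : r + p, c : c + p], return_counts=True)
        out.append(vals[np.argmax(counts)])
    return np.array(out)
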