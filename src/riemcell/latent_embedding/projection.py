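"""2-D embedding of latent vectors: Barnes–Hut t-SNE with cosine affinities."""

from __future__ import annotations

import numpy as np
from sklearn.manifold import TSNE

__all__ = ["tsne_project"]


def tsne_project(latents, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Project latent vectors to 2-D with Barnes–Hut t-SNE (θ = 0.5), cosine metric.

    Requires n > 3 × perplexity. The output is centered at the origin and is
    deterministic per seed. Degenerate input (all vectors identical) falls back
    to a seeded isotropic jitter so the contract "returns n points" holds.
    """
    X = np.stack([np.asarray(getattr(v, "values", v), dtype=float) for v in latents])
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(f"need n > 3 × perplexity ({3 * perplexity}), got n={n}")
    if np.allclose(X, X[0], atol=1e-12):
        rng = np.random.default_rng(seed)
        pts = 1e-4 * rng.standard_normal((n, 2))
        return pts - pts.mean(axis=0)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        metric="cosine",
        method="barnes_hut",
        angle=0.5,
        init="random",
        learning_rate="auto",
        random_state=seed,
        n_jobs=1,
    )
    pts = tsne.fit_transform(X).astype(float)
    return pts - pts.mean(axis=0)
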