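"""Cluster patch weight fields and render per-class probability maps.

K-Means groups the learned per-patch dictionary weights into C classes; a
Gaussian kernel over distance-to-center turns hard assignments into per-patch
class distributions, which fold back into a per-pixel probability map (with
overlap averaging and renormalization) plus an argmax label map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import tifffile
from sklearn.cluster import KMeans

from .patch_features import PatchGrid, fold_patches
from .riemannian_dictionary import WeightField

__all__ = [
    "ProbabilityMap",
    "LabelMap",
    "cluster_patch_weights",
    "soft_assignments",
    "render_probability_map",
    "write_maps",
]

DEFAULT_CLASSES = 5


@dataclass(frozen=True)
class ProbabilityMap:
    probs: np.ndarray  # H × W × C

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3:
            raise ValueError("probs must be H×W×C")
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = p.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def class_count(self) -> int:
        return self.probs.shape[-1]


@dataclass(frozen=True)
class LabelMap:
    labels: np.ndarray  # H × W int in {0..C-1}

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer array")
        object.__setattr__(self, "labels", lab)


def cluster_patch_weights(
    field: WeightField, C: int = DEFAULT_CLASSES, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """K-Means (k-means++ init, 10 restarts, best inertia) on per-patch weights.

    Returns (centers C × K, hard labels per patch in enumeration order).
    Assignment ties are broken by the lowest center index.
    """
    W = field.flat
    if C < 2:
        raise ValueError("C must be >= 2")
    if C > W.shape[0]:
        raise ValueError(f"C={C} exceeds the number of patches ({W.shape[0]})")
    if np.allclose(W, W[0], atol=1e-12):
        raise ValueError(
            "degenerate weight field: all patch weights identical, clustering undefined"
        )
    km = KMeans(n_clusters=C, init="k-means++", n_init=10, random_state=seed)
    km.fit(W)
    centers = km.cluster_centers_
    # re-assign explicitly so the lowest-index tie-break is guaranteed
    d2 = ((W[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    labels = np.argmin(d2, axis=1)
    return centers, labels


def soft_assignments(field: WeightField, centers: np.ndarray, tau: float | None = None) -> np.ndarray:
    """Per-patch class distributions q_c ∝ exp(−‖ω − center_c‖² / 2τ²).

    ``tau=None`` uses the median nearest-center distance (falling back to 1.0
    when that median is zero). Rows sum to 1.
    """
    W = field.flat
    centers = np.asarray(centers, dtype=float)
    d2 = ((W[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)  # n × C
    if tau is None:
        nearest = np.sqrt(d2.min(axis=1))
        tau = float(np.median(nearest)) or 1.0
    if tau <= 0:
        raise ValueError("tau must be positive")
    logits = -d2 / (2.0 * tau**2)
    logits -= logits.max(axis=1, keepdims=True)
    q = np.exp(logits)
    return q / q.sum(axis=1, keepdims=True)


def render_probability_map(
    grid: PatchGrid, soft: np.ndarray, out_shape: tuple[int, int]
) -> tuple[ProbabilityMap, LabelMap]:
    """Fold per-patch class distributions into a per-pixel probability map.

    Overlaps are averaged, then each pixel is renormalized to sum 1. The label
    map is the per-pixel argmax (lowest index wins ties).
    """
    soft = np.asarray(soft, dtype=float)
    maps = fold_patches(grid, soft, out_shape)  # C × H × W
    probs = np.moveaxis(maps, 0, -1)
    probs = probs / probs.sum(axis=-1, keepdims=True)
    labels = np.argmax(probs, axis=-1).astype(np.int32)
    return ProbabilityMap(probs=probs), LabelMap(labels=labels)


def write_maps(pmap: ProbabilityMap, lmap: LabelMap, out_prefix: str,
               meta: dict | None = None) -> dict[str, str]:
    """C-channel probability TIFF + 8-bit label PNG + JSON class legend."""
    paths = {
        "probs": f"{out_prefix}_probs.tif",
        "labels": f"{out_prefix}_labels.png",
        "legend": f"{out_prefix}_legend.json",
    }
    tifffile.imwrite(paths["probs"], np.moveaxis(pmap.probs, -1, 0).astype(np.float32),
                     photometric="minisblack")
    iio.imwrite(paths["labels"], lmap.labels.astype(np.uint8))
    legend = {"classes": list(range(pmap.class_count))}
    if meta:
        legend.update(meta)
    with open(paths["legend"], "w") as fh:
        json.dump(legend, fh, indent=2)
    return paths
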