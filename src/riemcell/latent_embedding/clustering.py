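"""Density clustering of 2-D embeddings and per-cluster morphology statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN

from .crops import CellCrop

__all__ = ["ClusterResult", "cluster_embeddings", "cluster_area_stats"]

DEFAULT_MIN_CLUSTER_FRAC = 0.02


@dataclass
class ClusterStats:
    n: int
    mean_area: float
    sem_area: float  # sd/√n with the n−1 denominator; 0.0 for singletons


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-cell; −1 = noise
    stats: dict[int, ClusterStats] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels.tolist()) - {-1}))


def cluster_embeddings(points, min_cluster_frac: float = DEFAULT_MIN_CLUSTER_FRAC) -> ClusterResult:
    """HDBSCAN on 2-D points with min cluster size = max(5, round(frac × n)).

    Noise is labeled −1. Rejects n < 10 and fractions outside (0, 1).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be an n × 2 array")
    n = pts.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 points, got {n}")
    if not (0.0 < min_cluster_frac < 1.0):
        raise ValueError("min_cluster_frac must be in (0, 1)")
    mcs = max(5, int(round(min_cluster_frac * n)))
    labels = HDBSCAN(min_cluster_size=mcs, copy=True).fit_predict(pts)
    return ClusterResult(labels=np.asarray(labels, dtype=int))


def cluster_area_stats(
    labels,
    crops: list[CellCrop],
    subsample_size: int | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Per non-noise cluster: n, mean original area, SEM = sd/√n (ddof = 1).

    ``subsample_size`` draws an equal-size seeded random sample from each
    cluster (clusters smaller than the requested size are used whole). Noise
    points (label −1) are excluded from every statistic.
    """
    lab = np.asarray(labels, dtype=int)
    if lab.shape[0] != len(crops):
        raise ValueError("labels and crops must be aligned")
    areas = np.array([c.orig_area for c in crops], dtype=float)
    rng = np.random.default_rng(seed)
    stats: dict[int, ClusterStats] = {}
    for cl in sorted(set(lab.tolist()) - {-1}):
        vals = areas[lab == cl]
        if subsample_size is not None and vals.size > subsample_size:
            vals = rng.choice(vals, size=subsample_size, replace=False)
        n = int(vals.size)
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        stats[int(cl)] = ClusterStats(n=n, mean_area=mean, sem_area=sem)
    return ClusterResult(labels=lab, stats=stats)
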