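"""Per-pixel feature stacks, patch unfolding/folding, and covariance grids.

An image becomes a stack of feature planes; the stack is unfolded into a
row-major grid of patches whose feature-by-pixel matrices yield one SPD
covariance descriptor per patch; per-patch values fold back into spatial maps
with overlap averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.ndimage import convolve1d

from .spd_core import SPDMatrix, patch_covariance

__all__ = [
    "FeatureStack",
    "PatchGrid",
    "feature_stack",
    "extract_patches",
    "patch_covariance_grid",
    "fold_patches",
    "write_stack",
]

DEFAULT_PATCH_SIZE = 8
DEFAULT_STRIDE = 4


@dataclass(frozen=True)
class FeatureStack:
    channels: np.ndarray  # d × H × W
    feature_names: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.channels, dtype=float)
        if c.ndim != 3 or c.shape[0] < 2:
            raise ValueError("channels must be d×H×W with d >= 2")
        if len(self.feature_names) != c.shape[0]:
            raise ValueError("feature_names length must equal channel count")
        object.__setattr__(self, "channels", c)

    @property
    def depth(self) -> int:
        return self.channels.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


@dataclass(frozen=True)
class PatchGrid:
    patch_size: int
    stride: int
    grid_dims: tuple[int, int]  # (rows, cols)
    patch_origins: tuple[tuple[int, int], ...]  # row-major (row, col) corners
    image_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return len(self.patch_origins)


def _d1(img: np.ndarray, axis: int) -> np.ndarray:
    # centered first difference, reflective borders
    return convolve1d(img, [0.5, 0.0, -0.5], axis=axis, mode="reflect")


def _d2(img: np.ndarray, axis: int) -> np.ndarray:
    return convolve1d(img, [1.0, -2.0, 1.0], axis=axis, mode="reflect")


def _random_bank(image: np.ndarray, depth: int, seed: int = 0) -> np.ndarray:
    """Seeded fixed random 5×5 conv bank — the hook for a learned front-end."""
    from scipy.ndimage import convolve

    rng = np.random.default_rng(seed)
    planes = [image]
    for _ in range(depth - 1):
        k = rng.standard_normal((5, 5))
        k -= k.mean()
        k /= np.abs(k).sum()
        planes.append(convolve(image, k, mode="reflect"))
    return np.stack(planes)


def feature_stack(image, feature_set: str = "derivatives6") -> FeatureStack:
    """Compute per-pixel feature planes for a single-channel image.

    ``"derivatives6"`` (default, fully deterministic): intensity, gradient
    magnitude, ∂x, ∂y, ∂xx, ∂yy by centered finite differences with reflective
    borders. ``"learned"``: a seeded fixed random convolution bank of depth 6
    standing in for a trainable front-end.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D single-channel")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if feature_set == "derivatives6":
        dx = _d1(img, axis=1)
        dy = _d1(img, axis=0)
        dxx = _d2(img, axis=1)
        dyy = _d2(img, axis=0)
        gmag = np.hypot(dx, dy)
        return FeatureStack(
            channels=np.stack([img, gmag, dx, dy, dxx, dyy]),
            feature_names=("intensity", "grad_mag", "dx", "dy", "dxx", "dyy"),
        )
    if feature_set == "learned":
        planes = _random_bank(img, depth=6)
        return FeatureStack(
            channels=planes,
            feature_names=tuple(["intensity"] + [f"conv{i}" for i in range(1, 6)]),
        )
    raise ValueError(f"unknown feature_set {feature_set!r}")


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, extent - patch + 1, stride))
    if origins[-1] != extent - patch:  # clamp one extra patch to the edge
        origins.append(extent - patch)
    return origins


def extract_patches(
    stack: FeatureStack, patch_size: int = DEFAULT_PATCH_SIZE, stride: int = DEFAULT_STRIDE
) -> tuple[PatchGrid, list[np.ndarray]]:
    """Unfold the stack into row-major patches of d × p² feature-by-pixel matrices.

    Columns of each X are in row-major pixel order. Right/bottom margins that
    do not fit a full patch are covered by one extra patch clamped to the edge.
    """
    H, W = stack.image_shape
    p, s = int(patch_size), int(stride)
    if p > min(H, W):
        raise ValueError(f"patch_size {p} exceeds image dimension {min(H, W)}")
    if s < 1:
        raise ValueError("stride must be >= 1")
    rows = _axis_origins(H, p, s)
    cols = _axis_origins(W, p, s)
    origins = tuple((r, c) for r in rows for c in cols)
    grid = PatchGrid(
        patch_size=p,
        stride=s,
        grid_dims=(len(rows), len(cols)),
        patch_origins=origins,
        image_shape=(H, W),
    )
    d = stack.depth
    Xs = [stack.channels[:, r : r + p, c : c + p].reshape(d, p * p) for r, c in origins]
    return grid, Xs


def patch_covariance_grid(stack: FeatureStack, grid: PatchGrid, eps: float = 1e-6) -> list[SPDMatrix]:
    """One SPD covariance descriptor per patch, in patch enumeration order."""
    p = grid.patch_size
    d = stack.depth
    return [
        patch_covariance(stack.channels[:, r : r + p, c : c + p].reshape(d, p * p), eps=eps)
        for r, c in grid.patch_origins
    ]


def fold_patches(grid: PatchGrid, per_patch_values, out_shape: tuple[int, int]) -> np.ndarray:
    """Paint each patch's value vector uniformly over its footprint; average overlaps.

    Returns a C × H × W stack where C is the value-vector length (scalars give
    C = 1). Every pixel must be covered at least once.
    """
    vals = np.atleast_2d(np.asarray(per_patch_values, dtype=float))
    if vals.shape[0] != grid.n_patches:
        raise ValueError(f"expected {grid.n_patches} value vectors, got {vals.shape[0]}")
    H, W = out_shape
    if (H, W) != grid.image_shape:
        raise ValueError(f"out_shape {out_shape} does not match grid {grid.image_shape}")
    C = vals.shape[1]
    p = grid.patch_size
    acc = np.zeros((C, H, W))
    cover = np.zeros((H, W))
    for (r, c), v in zip(grid.patch_origins, vals):
        acc[:, r : r + p, c : c + p] += v[:, None, None]
        cover[r : r + p, c : c + p] += 1.0
    if np.any(cover == 0):
        raise ValueError("coverage gap: grid does not tile the output shape")
    return acc / cover


def write_stack(stack_or_maps, path: str) -> None:
    """Write a feature stack or folded map stack as a multi-channel TIFF."""
    arr = np.asarray(getattr(stack_or_maps, "channels", stack_or_maps), dtype=np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
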