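"""Deterministic synthetic scenes, cell-crop populations, and SPD fixtures.

Every downstream module is testable without any download: textured elliptical
cells of distinct texture classes on a noisy background (with ground-truth
instance masks and class labels), populations of round vs elongated cell crops,
and random SPD matrices with controlled condition number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile

from .spd_core import SPDMatrix, project_to_spd

BACKGROUND_SIGMA = 0.05  # Gaussian background noise on [0,1] intensities
TEXTURE_CONTRAST = 0.35  # peak-to-peak texture amplitude, >= 0.3
MAX_PLACEMENT_ATTEMPTS = 1000

__all__ = [
    "SyntheticScene",
    "CellCropSample",
    "generate_texture_scene",
    "generate_cell_crops",
    "random_spd",
    "write_scene",
]


@dataclass(frozen=True)
class CellSpec:
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b), a >= b
    angle: float  # radians
    texture_class: int  # 1-based


@dataclass
class SyntheticScene:
    image: np.ndarray  # H×W float in [0,1]
    label_map: np.ndarray  # H×W int, 0 = background
    instance_masks: list[np.ndarray]  # boolean, pairwise disjoint
    cell_specs: list[CellSpec]

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class CellCropSample:
    crop: "CellCrop"  # noqa: F821 - imported lazily to avoid a cycle
    true_class: int


def _ellipse_mask(h: int, w: int, center, semi_axes, angle) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _texture(cls: int, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Class-specific texture field on [−.5, .5]·contrast around 0."""
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    amp = TEXTURE_CONTRAST / 2.0
    if cls == 1:  # oriented stripes
        return amp * np.sin(2 * np.pi * cc / 4.0)
    if cls == 2:  # isotropic speckle
        return amp * np.clip(rng.standard_normal((h, w)), -1.0, 1.0)
    if cls == 3:  # stripes at 60°, different frequency
        t = (cc * 0.5 + rr * np.sqrt(3) / 2)
        return amp * np.sin(2 * np.pi * t / 6.0)
    if cls == 4:  # stripes at 120°, finer
        t = (-cc * 0.5 + rr * np.sqrt(3) / 2)
        return amp * np.sin(2 * np.pi * t / 3.0)
    raise ValueError(f"unknown texture class {cls}")


def generate_texture_scene(
    width: int,
    height: int,
    n_cells: int,
    n_classes: int,
    seed: int,
    min_radius: float = 10.0,
    max_radius: float = 22.0,
) -> SyntheticScene:
    """Render elliptical textured cells on a noisy background, deterministically.

    Cells are placed by rejection sampling (fully inside the frame, < 20%
    footprint overlap with already placed cells, at most
    ``MAX_PLACEMENT_ATTEMPTS`` attempts each); residual overlap is resolved by
    clipping later cells with earlier masks. Texture classes cycle 1..n_classes.
    """
    if not (1 <= n_classes <= 4):
        raise ValueError("n_classes must be in 1..4")
    if width < 32 or height < 32:
        raise ValueError("width and height must be >= 32")
    rng = np.random.default_rng(seed)
    h, w = height, width
    image = np.clip(0.5 + BACKGROUND_SIGMA * rng.standard_normal((h, w)), 0.0, 1.0)
    label_map = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    masks: list[np.ndarray] = []
    specs: list[CellSpec] = []

    for i in range(n_cells):
        cls = 1 + (i % n_classes)
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            a = rng.uniform(min_radius, max_radius)
            b = rng.uniform(0.6 * a, a)
            angle = rng.uniform(0, np.pi)
            cy = rng.uniform(a, h - a)
            cx = rng.uniform(a, w - a)
            mask = _ellipse_mask(h, w, (cy, cx), (a, b), angle)
            if not mask.any():
                continue
            overlap = (mask & occupied).sum() / mask.sum()
            if overlap < 0.2:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n_cells} after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts; reduce n_cells"
            )
        mask &= ~occupied  # clip by earlier cells: priority by placement order
        tex = 0.5 + _texture(cls, h, w, rng) + 0.02 * rng.standard_normal((h, w))
        image[mask] = np.clip(tex[mask], 0.0, 1.0)
        label_map[mask] = cls
        occupied |= mask
        masks.append(mask)
        specs.append(CellSpec((cy, cx), (a, b), angle, cls))

    return SyntheticScene(image=image, label_map=label_map, instance_masks=masks, cell_specs=specs)


def generate_cell_crops(n: int, class_fractions, seed: int) -> list[CellCropSample]:
    """Synthetic single-cell crops: class 0 round, class 1+ increasingly elongated.

    Each crop is 128×128 with an elliptical padding mask, textured interior,
    random rotation and size jitter, normalized to the (x−0.5)/0.5 convention.
    Class counts follow ``class_fractions`` up to rounding; deterministic per
    seed.
    """
    from .latent_embedding.crops import CellCrop  # local import avoids a cycle

    fr = np.asarray(class_fractions, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if fr.ndim != 1 or fr.size < 1 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-8:
        raise ValueError("class_fractions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    # largest-remainder rounding of per-class counts
    raw = fr * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1

    classes = np.repeat(np.arange(fr.size), counts)
    rng.shuffle(classes)

    size = 128
    samples: list[CellCropSample] = []
    for cls in classes:
        if cls == 0:  # round: axis ratio ~ 1
            a = rng.uniform(22, 34)
            b = a * rng.uniform(0.9, 1.0)
        else:  # elongated: axis ratio >= 3
            a = rng.uniform(42, 58)
            b = a / rng.uniform(3.0, 4.0)
        angle = rng.uniform(0, np.pi)
        cy = size / 2 + rng.uniform(-4, 4)
        cx = size / 2 + rng.uniform(-4, 4)
        mask = _ellipse_mask(size, size, (cy, cx), (a, b), angle)
        intensity = np.zeros((size, size))
        base = rng.uniform(0.55, 0.8)
        tex = base + 0.08 * rng.standard_normal((size, size))
        intensity[mask] = np.clip(tex[mask], 0.0, 1.0)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        y0, y1 = int(rows[0]), int(rows[-1]) + 1
        x0, x1 = int(cols[0]), int(cols[-1]) + 1
        crop = CellCrop(
            pixels=(intensity - 0.5) / 0.5,
            padding_mask=mask,
            orig_size=(y1 - y0, x1 - x0),
            orig_area=int(mask.sum()),
            bbox=(y0, y1, x0, x1),
        )
        samples.append(CellCropSample(crop=crop, true_class=int(cls)))
    return samples


def random_spd(d: int, cond_max: float, seed: int) -> SPDMatrix:
    """Random SPD matrix with eigenvalues in [1/cond_max, 1] (up to scale)."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if cond_max < 1:
        raise ValueError("cond_max must be >= 1")
    rng = np.random.default_rng(seed)
    if cond_max == 1.0:
        return SPDMatrix(np.eye(d))
    lo = np.log(1.0 / cond_max)
    lam = np.exp(rng.uniform(lo, 0.0, size=d))
    if d >= 2:  # pin the extremes so the condition number is realized
        lam[0], lam[-1] = 1.0 / cond_max, 1.0
        rng.shuffle(lam)
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    A = (Q * lam) @ Q.T
    return project_to_spd(A, eps=min(1.0 / cond_max, 1e-6))


def write_scene(scene: SyntheticScene, out_prefix: str) -> dict[str, str]:
    """Write image TIFF, 16-bit instance-label TIFF, and a JSON spec sidecar."""
    paths = {
        "image": f"{out_prefix}_image.tif",
        "labels": f"{out_prefix}_labels.tif",
        "specs": f"{out_prefix}_specs.json",
    }
    tifffile.imwrite(paths["image"], scene.image.astype(np.float32))
    inst = np.zeros(scene.shape, dtype=np.uint16)
    for i, m in enumerate(scene.instance_masks, start=1):
        inst[m] = i
    tifffile.imwrite(paths["labels"], inst)
    with open(paths["specs"], "w") as fh:
        json.dump(
            [
                {
                    "center": list(s.center),
                    "semi_axes": list(s.semi_axes),
                    "angle": s.angle,
                    "class": s.texture_class,
                }
                for s in scene.cell_specs
            ],
            fh,
            indent=2,
        )
    return paths
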