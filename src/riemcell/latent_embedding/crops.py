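"""Masked, normalized 128×128 single-cell crops from instance label images."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

CROP_SIZE = 128

__all__ = ["CellCrop", "crop_cells", "CROP_SIZE"]


@dataclass
class CellCrop:
    """A single cell: masked intensities in the (x−0.5)/0.5 convention.

    ``pixels`` is 128×128 with background/letterbox at −1 (i.e. raw 0);
    ``padding_mask`` is true on real cell pixels; ``orig_size``/``orig_area``
    record the source bounding box and mask before resizing; ``bbox`` is the
    half-open (y0, y1, x0, x1) box in the source image.
    """

    pixels: np.ndarray
    padding_mask: np.ndarray
    orig_size: tuple[int, int]
    orig_area: int
    bbox: tuple[int, int, int, int]

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        pm = np.asarray(self.padding_mask, dtype=bool)
        if px.shape != (CROP_SIZE, CROP_SIZE) or pm.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"crop arrays must be {CROP_SIZE}×{CROP_SIZE}")
        if not np.all(np.isfinite(px)):
            raise ValueError("crop pixels must be finite")
        if not pm.any():
            raise ValueError("padding mask must contain at least one true pixel")
        y0, y1, x0, x1 = self.bbox
        if self.orig_area > (y1 - y0) * (x1 - x0):
            raise ValueError("orig_area exceeds the bounding-box area")
        self.pixels = px
        self.padding_mask = pm


def crop_cells(image, instance_labels) -> list[CellCrop]:
    """Extract one masked, letterboxed 128×128 crop per instance label.

    For each label ≥ 1 (ascending order): tight bounding box, pixels outside
    the instance mask zeroed before normalization, aspect-preserving resize to
    fit 128×128 (bilinear for intensities, nearest for the mask) with centered
    zero letterboxing. Empty labels are skipped with a warning.
    """
    img = np.asarray(image, dtype=float)
    lab = np.asarray(instance_labels)
    if img.shape != lab.shape:
        raise ValueError("image and label image must share a shape")
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("instance_labels must be an integer label image")
    crops: list[CellCrop] = []
    for label in np.unique(lab):
        if label < 1:
            continue
        mask = lab == label
        if not mask.any():  # pragma: no cover - unique() precludes this
            warnings.warn(f"instance {label} has an empty mask; skipped")
            continue
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        y0, y1 = int(rows[0]), int(rows[-1]) + 1
        x0, x1 = int(cols[0]), int(cols[-1]) + 1
        sub = np.where(mask[y0:y1, x0:x1], img[y0:y1, x0:x1], 0.0)
        submask = mask[y0:y1, x0:x1]
        h, w = sub.shape
        scale = CROP_SIZE / max(h, w)
        nh = max(1, int(round(h * scale)))
        nw = max(1, int(round(w * scale)))
        rimg = resize(sub, (nh, nw), order=1, anti_aliasing=scale < 1, preserve_range=True)
        rmask = resize(submask.astype(float), (nh, nw), order=0, preserve_range=True) > 0.5
        canvas = np.zeros((CROP_SIZE, CROP_SIZE))
        mcanvas = np.zeros((CROP_SIZE, CROP_SIZE), dtype=bool)
        oy = (CROP_SIZE - nh) // 2
        ox = (CROP_SIZE - nw) // 2
        canvas[oy : oy + nh, ox : ox + nw] = rimg
        mcanvas[oy : oy + nh, ox : ox + nw] = rmask
        if not mcanvas.any():
            warnings.warn(f"instance {label} vanished after resize; skipped")
            continue
        crops.append(
            CellCrop(
                pixels=(canvas - 0.5) / 0.5,
                padding_mask=mcanvas,
                orig_size=(h, w),
                orig_area=int(mask.sum()),
                bbox=(y0, y1, x0, x1),
            )
        )
    return crops
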