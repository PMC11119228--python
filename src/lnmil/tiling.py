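"""Tissue detection and patch tiling of slides into bags.

A slide becomes a :class:`Bag` of non-overlapping fixed-size patches covering
every tissue region; the bag inherits the slide's LNM label.  Tissue detection
is Otsu thresholding on the HSV saturation channel followed by small-object
removal, which is the conventional recipe for H&E slides on a near-white
background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects


@dataclass
class Bag:
    """All retained patches of one slide, row-major, 0-based half-open coords."""

    slide_id: str
    patient_id: str
    inherited_label: int
    patch_size: int
    anchors: list[tuple[int, int]] = field(default_factory=list)  # (x0, y0)
    patches: np.ndarray | None = None  # (N, p, p, 3) uint8

    def __len__(self) -> int:
        return len(self.anchors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": self.slide_id,
                "x0": [a[0] for a in self.anchors],
                "y0": [a[1] for a in self.anchors],
                "patch_size": self.patch_size,
            }
        )


def detect_tissue(slide: np.ndarray, min_object_area: int = 256 * 256,
                  sat_floor: float = 0.05) -> np.ndarray:
    """Binary tissue mask: Otsu on saturation, then drop objects < one patch.

    Near-white rasters (maximum saturation below ``sat_floor``) yield an empty
    mask, since Otsu on a constant channel is meaningless.  Deterministic and
    idempotent.
    """
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[2] != 3:
        raise ValueError("detect_tissue expects an RGB raster (H, W, 3)")
    sat = color.rgb2hsv(slide)[:, :, 1]
    if float(sat.max()) < sat_floor:
        return np.zeros(slide.shape[:2], dtype=bool)
    mask = sat > threshold_otsu(sat)
    if min_object_area > 0:
        try:
            mask = remove_small_objects(mask, max_size=min_object_area - 1)
        except TypeError:  # older scikit-image
            mask = remove_small_objects(mask, min_size=min_object_area)
    return mask


def tile(slide: np.ndarray, mask: np.ndarray, patch_size: int = 256,
         min_tissue_frac: float = 0.5, *, slide_id: str = "", patient_id: str = "",
         label: int = 0) -> Bag:
    """Tile ``slide`` on a non-overlapping grid, keeping tissue-rich patches.

    A grid cell ``[x0, x0+p) x [y0, y0+p)`` is kept iff the fraction of mask
    pixels inside it is >= ``min_tissue_frac``.  Trailing partial rows/columns
    are dropped.  Anchors are sorted row-major.
    """
    if not 0.0 <= min_tissue_frac <= 1.0:
        raise ValueError("min_tissue_frac must be in [0, 1]")
    slide = np.asarray(slide)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != slide.shape[:2]:
        raise ValueError("mask and slide dimensions differ")
    H, W = mask.shape
    p = patch_size
    if p < 1 or H // p == 0 or W // p == 0:
        raise ValueError("patch_size larger than raster")
    bag = Bag(slide_id=slide_id, patient_id=patient_id, inherited_label=int(label),
              patch_size=p)
    if not mask.any() and min_tissue_frac > 0:
        warnings.warn(f"slide {slide_id or '<unnamed>'}: empty tissue mask, empty bag")
        bag.patches = np.zeros((0, p, p, slide.shape[2]), dtype=slide.dtype)
        return bag
    keep_patches = []
    for gy in range(H // p):
        for gx in range(W // p):
            y0, x0 = gy * p, gx * p
            frac = mask[y0 : y0 + p, x0 : x0 + p].mean()
            if frac >= min_tissue_frac:
                bag.anchors.append((x0, y0))
                keep_patches.append(slide[y0 : y0 + p, x0 : x0 + p])
    bag.patches = (
        np.stack(keep_patches)
        if keep_patches
        else np.zeros((0, p, p, slide.shape[2]), dtype=slide.dtype)
    )
    return bag


def patch_mask_fractions(bag: Bag, mask: np.ndarray) -> np.ndarray:
    """Per-patch fraction of ``mask`` pixels (e.g. evidence coverage per patch)."""
    mask = np.asarray(mask, dtype=bool)
    p = bag.patch_size
    return np.array([mask[y0 : y0 + p, x0 : x0 + p].mean() for x0, y0 in bag.anchors])
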