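"""Attention heatmaps and top-attention patch export.

Per-patch attention scores are min-max normalized over the bag and painted
over the corresponding patch rectangles; everything outside retained patches
is transparent.  Constant-score bags normalize to all zeros, so a bag with no
informative patch renders visually null.  The colormap is fixed ("inferno")
so rendering the same inputs always produces identical PNG bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .model import AttentionResult
from .tiling import Bag

COLORMAP = "inferno"


def minmax_normalize(scores) -> np.ndarray:
    """(s - min) / (max - min); a constant vector maps to all zeros."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        return np.zeros_like(s)
    return (s - lo) / (hi - lo)


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) float in [0, 1]
    alpha: np.ndarray  # (H, W) bool, True where a patch was painted
    colormap: str = COLORMAP

    def to_rgba(self) -> np.ndarray:
        cmap = colormaps[self.colormap]
        rgba = (cmap(self.values) * 255).astype(np.uint8)
        rgba[:, :, 3] = np.where(self.alpha, 255, 0)
        return rgba

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.to_rgba(), mode="RGBA").save(path)


def render_heatmap(bag: Bag, result: AttentionResult, shape: tuple[int, int]) -> Heatmap:
    """Paint each patch rectangle with its min-max-normalized attention score."""
    scores = np.asarray(result.scores, dtype=float)
    if len(scores) != len(bag):
        raise ValueError("scores do not align 1:1 with bag patches")
    norm = minmax_normalize(scores)
    values = np.zeros(shape, dtype=float)
    alpha = np.zeros(shape, dtype=bool)
    p = bag.patch_size
    for (x0, y0), v in zip(bag.anchors, norm):
        values[y0 : y0 + p, x0 : x0 + p] = v
        alpha[y0 : y0 + p, x0 : x0 + p] = True
    return Heatmap(values=values, alpha=alpha)


def top_patches(bag: Bag, result: AttentionResult, k: int):
    """The k highest-attention patches, ties broken row-major by coordinate.

    Returns ``(patches, anchors, scores)`` sorted by attention descending.
    """
    scores = np.asarray(result.scores, dtype=float)
    if len(scores) != len(bag):
        raise ValueError("scores do not align 1:1 with bag patches")
    if k > len(bag):
        raise ValueError(f"k={k} exceeds bag size {len(bag)}")
    ys = np.array([a[1] for a in bag.anchors])
    xs = np.array([a[0] for a in bag.anchors])
    order = np.lexsort((xs, ys, -scores))[:k]
    return (
        bag.patches[order],
        [bag.anchors[i] for i in order],
        scores[order],
    )


def export_scores_csv(bag: Bag, result: AttentionResult, path: str | Path) -> None:
    """CSV of (slide_id, x0, y0, AS, normalized_AS), one row per patch."""
    import pandas as pd

    norm = minmax_normalize(result.scores)
    pd.DataFrame(
        {
            "slide_id": bag.slide_id,
            "x0": [a[0] for a in bag.anchors],
            "y0": [a[1] for a in bag.anchors],
            "attention_score": np.asarray(result.scores, dtype=float),
            "normalized_attention_score": norm,
        }
    ).to_csv(path, index=False)


def export_patch_gallery(bag: Bag, result: AttentionResult, k: int, outdir: str | Path) -> list[Path]:
    """Write the top-k patches as PNGs named by rank and anchor."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patches, anchors, _scores = top_patches(bag, result, k)
    paths = []
    for rank, (img, (x0, y0)) in enumerate(zip(patches, anchors), start=1):
        p = outdir / f"{bag.slide_id}_rank{rank:02d}_x{x0}_y{y0}.png"
        Image.fromarray(img).save(p)
        paths.append(p)
    return paths
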