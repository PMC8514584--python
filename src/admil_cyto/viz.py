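"""Attention-map rendering.

For a classified bag, each retained tile of a source image is shaded by its
attention weight through a sequential colormap (blue = low, through yellow to
red = high) and alpha-blended onto the image.  Tiles that were filtered out
during extraction stay unshaded.  Rendering is a pure function of the image,
the weights and the normalization choice, so a re-render is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

from .extraction import PatchInstance, SpecimenImage
from .model import BagPrediction

NORMALIZATIONS = ("per_image", "per_bag")


@dataclass
class AttentionMap:
    image_id: str
    weight_grid: np.ndarray       # (rows, cols) raw a_k; NaN where no instance
    normalized_grid: np.ndarray   # same shape, weights / chosen max
    overlay: np.ndarray           # (H, W, 3) uint8 rendered image

    def to_frame(self) -> pd.DataFrame:
        rows = []
        nr, nc = self.weight_grid.shape
        for r in range(nr):
            for c in range(nc):
                if np.isfinite(self.weight_grid[r, c]):
                    rows.append({"grid_row": r, "grid_col": c,
                                 "raw_weight": float(self.weight_grid[r, c]),
                                 "normalized_weight": float(self.normalized_grid[r, c])})
        return pd.DataFrame(rows)


def render_attention_map(image: SpecimenImage, prediction: BagPrediction,
                         bag_instances: list[PatchInstance],
                         normalization: str = "per_image",
                         cmap: str = "jet", alpha: float = 0.4) -> AttentionMap:
    """Overlay a bag's attention weights onto one of its source images.

    ``bag_instances`` must be the bag's instances in the exact order the
    prediction's attention weights were produced; instances from other images
    of the bag are used only for per-bag normalization.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    weights = prediction.attention_weights
    if weights is None:
        raise ValueError("prediction carries no attention weights (mean pooling?)")
    if len(weights) != len(bag_instances):
        raise ValueError("attention weights and bag instances are misaligned "
                         f"({len(weights)} vs {len(bag_instances)})")

    mine = [(inst, float(a)) for inst, a in zip(bag_instances, weights)
            if inst.source_image_id == image.image_id]
    if not mine:
        raise ValueError(f"no instances of image {image.image_id!r} in this bag")
    patch = mine[0][0].pixels.shape[0]
    h, w = image.pixels.shape[:2]
    grid = np.full((h // patch, w // patch), np.nan)
    for inst, a in mine:
        grid[inst.grid_row, inst.grid_col] = a

    if normalization == "per_image":
        denom = max(a for _, a in mine)
    else:
        denom = float(np.max(weights))
    norm = grid / denom if denom > 0 else grid

    colors = matplotlib.colormaps[cmap]
    overlay = image.pixels.astype(np.float64).copy()
    for inst, _ in mine:
        v = norm[inst.grid_row, inst.grid_col]
        rgb = np.array(colors(float(np.clip(v, 0.0, 1.0)))[:3]) * 255.0
        y0, x0 = inst.origin_y, inst.origin_x
        overlay[y0:y0 + patch, x0:x0 + patch] = (
            (1.0 - alpha) * overlay[y0:y0 + patch, x0:x0 + patch] + alpha * rgb)
    return AttentionMap(image_id=image.image_id, weight_grid=grid,
                        normalized_grid=norm,
                        overlay=np.clip(np.rint(overlay), 0, 255).astype(np.uint8))
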