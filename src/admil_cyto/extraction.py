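"""Patch-instance generation from specimen images.

Each microscopy field is tiled into a non-overlapping grid of square patches.
The field is binarised once with Otsu's method (cells stain darker than the
illuminated background, so foreground = intensity strictly below the
threshold) and a tile is kept as an instance only if more than
``min_cell_fraction`` of its pixels are foreground.  Partial tiles at the
right/bottom edges are dropped rather than padded, so the candidate count is
always ``floor(W/p) * floor(H/p)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

SUPPORTED_PATCH_SIZES = (64, 96, 128)


@dataclass
class SpecimenImage:
    """One RGB microscopy field with its case ID and weak (bag) label."""

    image_id: str
    case_id: str
    label: str  # "benign" | "malignant"
    pixels: np.ndarray  # (H, W, 3) uint8

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class ExtractionConfig:
    patch_size: int = 64
    min_cell_fraction: float = 0.10
    edge_policy: str = "drop_partial"

    def __post_init__(self):
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.patch_size not in SUPPORTED_PATCH_SIZES:
            logger.warning("patch_size %d is outside the evaluated sizes %s",
                           self.patch_size, SUPPORTED_PATCH_SIZES)
        if not (0.0 <= self.min_cell_fraction < 1.0):
            raise ValueError("min_cell_fraction must lie in [0, 1)")
        if self.edge_policy != "drop_partial":
            raise ValueError("only edge_policy='drop_partial' is supported")


@dataclass
class PatchInstance:
    """A retained patch: the unit fed to the CNN backbone."""

    pixels: np.ndarray  # (p, p, 3) uint8
    source_image_id: str
    grid_row: int
    grid_col: int
    origin_x: int
    origin_y: int
    foreground_fraction: float


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance, Y = 0.299 R + 0.587 G + 0.114 B, rounded half-up."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("to_grayscale expects an (H, W, 3) RGB array")
    y = (0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2])
    return np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int | None:
    """Otsu's threshold over the 256-bin histogram.

    Returns the level ``t`` maximising the between-class variance when pixels
    with intensity strictly below ``t`` are called foreground (ties broken
    toward the lowest level).  A constant image admits no split and yields
    ``None``, meaning "no foreground".
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("otsu_threshold requires a non-empty image")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # class 0 = pixels < t for t = 0..255 -> cumulative sums up to t-1
    w0 = np.concatenate([[0.0], np.cumsum(hist)])[:256]
    s0 = np.concatenate([[0.0], np.cumsum(hist * levels)])[:256]
    w1 = n - w0
    s1 = (hist * levels).sum() - s0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, s0 / w0, 0.0)
        mu1 = np.where(w1 > 0, s1 / w1, 0.0)
    var_between = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = 0.0
    best = int(np.argmax(var_between))
    if var_between[best] <= 0.0:
        return None
    return best


def extract_instances(image: SpecimenImage, config: ExtractionConfig | None = None
                      ) -> list[PatchInstance]:
    """Tile one field into retained patch instances (row-major order)."""
    config = config or ExtractionConfig()
    p = config.patch_size
    h, w = image.pixels.shape[:2]
    if h < p or w < p:
        logger.warning("image %s (%dx%d) smaller than patch size %d; no instances",
                       image.image_id, w, h, p)
        return []
    gray = to_grayscale(image.pixels)
    t = otsu_threshold(gray)
    if t is None:
        logger.warning("image %s is constant; no foreground, no instances", image.image_id)
        return []
    fg = gray < t
    out: list[PatchInstance] = []
    for r in range(h // p):
        for c in range(w // p):
            y0, x0 = r * p, c * p
            frac = float(fg[y0:y0 + p, x0:x0 + p].mean())
            if frac > config.min_cell_fraction:
                out.append(PatchInstance(
                    pixels=image.pixels[y0:y0 + p, x0:x0 + p].copy(),
                    source_image_id=image.image_id,
                    grid_row=r, grid_col=c, origin_x=x0, origin_y=y0,
                    foreground_fraction=frac))
    return out


def candidate_grid(width: int, height: int, patch_size: int) -> tuple[int, int]:
    """(n_rows, n_cols) of the candidate tiling before foreground filtering."""
    return height // patch_size, width // patch_size


# ---------------------------------------------------------------------------
# manifest I/O

def read_manifest(path) -> pd.DataFrame:
    """Read a case manifest CSV with columns case_id, image_path, label."""
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = {"case_id", "image_path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    bad = set(df["label"]) - {"benign", "malignant"}
    if bad:
        raise ValueError(f"manifest labels must be benign/malignant, found {sorted(bad)}")
    return df


def load_images(manifest: pd.DataFrame, root=None) -> list[SpecimenImage]:
    root = Path(root) if root is not None else None
    images = []
    for row in manifest.itertuples(index=False):
        path = Path(row.image_path)
        if root is not None and not path.is_absolute():
            path = root / path
        arr = np.asarray(Image.open(path).convert("RGB"))
        images.append(SpecimenImage(image_id=path.stem, case_id=str(row.case_id),
                                    label=row.label, pixels=arr))
    return images


def instances_to_frame(instances: list[PatchInstance]) -> pd.DataFrame:
    """Tabulate retained instances (one row each) for the instance manifest."""
    return pd.DataFrame([{
        "image_id": i.source_image_id, "grid_row": i.grid_row, "grid_col": i.grid_col,
        "origin_x": i.origin_x, "origin_y": i.origin_y,
        "foreground_fraction": i.foreground_fraction, "retained": True,
    } for i in instances])
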