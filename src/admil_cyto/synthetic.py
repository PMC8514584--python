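"""Seeded generator of synthetic Papanicolaou-like specimen fields.

Real cytology specimens cannot be redistributed, so experiments and tests run
on synthetic fields: a bright, faintly pink background scattered with darker
elliptical nuclei.  Benign-like nuclei are small, round-ish and moderately
stained; malignant-like nuclei are larger, darker and more eccentric —
echoing how malignant lung cells present (less cytoplasm, irregular, darker
nuclei).  Malignant cases plant malignant-like nuclei in every image;
benign cases contain none, so the per-case weak label is exact and the
planted nuclei provide a ground truth for attention evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse

from .extraction import SpecimenImage, SUPPORTED_PATCH_SIZES


class ConfigError(ValueError):
    """Raised when a SynthConfig field is out of contract."""


Range = tuple[float, float]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the source geometry (1280 x 960 fields); ``small_profile``
    gives a 256 x 192 variant for desk-scale training runs.
    """

    image_width: int = 1280
    image_height: int = 960
    n_cases: int = 40
    malignant_fraction: float = 0.5
    images_per_case: tuple[int, int] = (2, 3)
    cells_per_image: tuple[int, int] = (40, 80)
    benign_nucleus_radius: Range = (6.0, 10.0)
    malignant_nucleus_radius: Range = (12.0, 17.0)
    benign_intensity: Range = (110.0, 170.0)
    malignant_intensity: Range = (40.0, 90.0)
    malignant_cell_fraction_in_malignant_image: float = 0.3
    background_intensity: float = 230.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        def _range_ok(name, r, lo=None, hi=None):
            if r[0] > r[1]:
                raise ConfigError(f"{name}: lower bound exceeds upper bound")
            if lo is not None and r[0] < lo or hi is not None and r[1] > hi:
                raise ConfigError(f"{name}: values must lie in [{lo}, {hi}]")

        if self.n_cases < 1:
            raise ConfigError("n_cases must be at least 1")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ConfigError("malignant_fraction must lie in [0, 1]")
        _range_ok("images_per_case", self.images_per_case, lo=1)
        _range_ok("cells_per_image", self.cells_per_image, lo=1)
        _range_ok("benign_nucleus_radius", self.benign_nucleus_radius, lo=1)
        _range_ok("malignant_nucleus_radius", self.malignant_nucleus_radius, lo=1)
        if self.malignant_nucleus_radius[0] <= self.benign_nucleus_radius[1]:
            raise ConfigError("malignant_nucleus_radius: range must lie strictly above "
                              "benign_nucleus_radius (separable signal)")
        _range_ok("benign_intensity", self.benign_intensity, lo=0, hi=255)
        _range_ok("malignant_intensity", self.malignant_intensity, lo=0, hi=255)
        if not 0.0 <= self.background_intensity <= 255.0:
            raise ConfigError("background_intensity must lie in [0, 255]")
        if self.background_intensity <= max(self.benign_intensity[1],
                                            self.malignant_intensity[1]):
            raise ConfigError("background_intensity: must be strictly above both cell "
                              "intensity ranges (cells are darker than the background)")
        if not 0.0 < self.malignant_cell_fraction_in_malignant_image <= 1.0:
            raise ConfigError("malignant_cell_fraction_in_malignant_image: must be in "
                              "(0, 1]; zero would leave malignant cases without signal")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def small_profile(**overrides) -> SynthConfig:
    """256 x 192 fields with proportionally denser cells, for fast experiments."""
    base = dict(image_width=256, image_height=192, cells_per_image=(12, 20))
    base.update(overrides)
    return SynthConfig(**base)


@dataclass
class CellRecord:
    cy: float
    cx: float
    r_major: float
    r_minor: float
    angle: float
    intensity: float
    malignant: bool


@dataclass
class GroundTruth:
    """Per-image cell records plus derived per-patch labels."""

    cells: dict[str, list[CellRecord]] = field(default_factory=dict)

    def patch_labels(self, image_id: str, image_shape: tuple[int, int],
                     patch_size: int) -> np.ndarray:
        """Boolean grid (n_rows, n_cols): True where any malignant-like cell
        center falls inside the tile."""
        h, w = image_shape
        rows, cols = h // patch_size, w // patch_size
        grid = np.zeros((rows, cols), dtype=bool)
        for cell in self.cells[image_id]:
            if not cell.malignant:
                continue
            r, c = int(cell.cy) // patch_size, int(cell.cx) // patch_size
            if 0 <= r < rows and 0 <= c < cols:
                grid[r, c] = True
        return grid

    def to_json(self, path, image_shapes: dict[str, tuple[int, int]]) -> None:
        payload = {}
        for image_id, cells in self.cells.items():
            payload[image_id] = {
                "cells": [asdict(c) for c in cells],
                "patch_labels": {
                    str(p): self.patch_labels(image_id, image_shapes[image_id], p)
                            .astype(int).tolist()
                    for p in SUPPORTED_PATCH_SIZES
                    if min(image_shapes[image_id]) >= p
                },
            }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SyntheticDataset:
    images: list[SpecimenImage]
    manifest: pd.DataFrame  # case_id, image_path, label
    ground_truth: GroundTruth
    config: SynthConfig


def _render_image(rng: np.random.Generator, cfg: SynthConfig, n_cells: int,
                  n_malignant_cells: int) -> tuple[np.ndarray, list[CellRecord]]:
    h, w = cfg.image_height, cfg.image_width
    bg = cfg.background_intensity
    # faint pink background tint, as in Pap-stained brightfield
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[..., 0] = bg
    canvas[..., 1] = bg * 0.94
    canvas[..., 2] = bg * 0.97
    n_mal = min(n_malignant_cells, n_cells)
    cells: list[CellRecord] = []
    for i in range(n_cells):
        malignant = i < n_mal
        if malignant:
            r_major = rng.uniform(*cfg.malignant_nucleus_radius)
            r_minor = r_major * rng.uniform(0.5, 0.95)   # higher eccentricity jitter
            inten = rng.uniform(*cfg.malignant_intensity)
        else:
            r_major = rng.uniform(*cfg.benign_nucleus_radius)
            r_minor = r_major * rng.uniform(0.85, 1.0)
            inten = rng.uniform(*cfg.benign_intensity)
        margin = r_major + 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        angle = rng.uniform(0.0, np.pi)
        rr, cc = ellipse(cy, cx, r_major, r_minor, shape=(h, w), rotation=angle)
        # bluish-purple nuclear chromatin, darker for malignant-like cells
        canvas[rr, cc, 0] = inten * 0.75
        canvas[rr, cc, 1] = inten * 0.70
        canvas[rr, cc, 2] = inten
        cells.append(CellRecord(cy=cy, cx=cx, r_major=r_major, r_minor=r_minor,
                                angle=angle, intensity=inten, malignant=malignant))
    if cfg.noise_sd > 0:
        canvas += rng.normal(0.0, cfg.noise_sd, size=canvas.shape)
    return np.clip(canvas, 0, 255).astype(np.uint8), cells


def generate_dataset(config: SynthConfig, out_dir=None) -> SyntheticDataset:
    """Generate images, case manifest and ground truth; deterministic in the seed.

    When ``out_dir`` is given, PNG images, ``manifest.csv`` and
    ``ground_truth.json`` are written there.
    """
    rng = np.random.default_rng(config.seed)
    n_mal_cases = round(config.n_cases * config.malignant_fraction)
    labels = ["malignant"] * n_mal_cases + ["benign"] * (config.n_cases - n_mal_cases)
    rng.shuffle(labels)

    images: list[SpecimenImage] = []
    rows = []
    gt = GroundTruth()
    for ci, label in enumerate(labels):
        case_id = f"case{ci:03d}"
        n_images = int(rng.integers(config.images_per_case[0],
                                    config.images_per_case[1] + 1))
        for ii in range(n_images):
            image_id = f"{case_id}_img{ii}"
            n_cells = int(rng.integers(config.cells_per_image[0],
                                       config.cells_per_image[1] + 1))
            if label == "malignant":
                n_mal = max(1, round(
                    config.malignant_cell_fraction_in_malignant_image * n_cells))
            else:
                n_mal = 0
            pixels, cells = _render_image(rng, config, n_cells, n_mal)
            images.append(SpecimenImage(image_id=image_id, case_id=case_id,
                                        label=label, pixels=pixels))
            gt.cells[image_id] = cells
            rows.append({"case_id": case_id, "image_path": f"{image_id}.png",
                         "label": label})
    manifest = pd.DataFrame(rows)

    ds = SyntheticDataset(images=images, manifest=manifest, ground_truth=gt,
                          config=config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img in images:
            Image.fromarray(img.pixels).save(out / f"{img.image_id}.png")
        manifest.to_csv(out / "manifest.csv", index=False)
        shapes = {img.image_id: img.pixels.shape[:2] for img in images}
        gt.to_json(out / "ground_truth.json", shapes)
    return ds
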