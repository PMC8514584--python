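"""Desk-scale end-to-end experiments on synthetic specimens.

These drive the whole pipeline — generate fields, extract instances, build
bags, run case-stratified cross-validation — at sizes a single CPU handles in
minutes.  They back the worked examples and the reproduction script; the
methods note discusses what the synthetic conditions do and do not show.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bags import Bag, build_bags, make_cv_splits
from .extraction import ExtractionConfig, extract_instances
from .metrics import compute_metrics, results_to_confusion
from .model import Checkpoint
from .synthetic import SyntheticDataset, generate_dataset, small_profile
from .training import CaseResult, TrainConfig, predict_bag, run_cross_validation

logger = logging.getLogger(__name__)


@dataclass
class ExperimentResult:
    regime: str
    seed: int
    balanced_accuracy: float
    accuracy: float
    sensitivity: float
    specificity: float
    case_results: list[CaseResult] = field(default_factory=list)
    checkpoints: list[Checkpoint] = field(default_factory=list)


def build_synthetic_bags(n_cases: int, seed: int, patch_size: int = 64
                         ) -> tuple[SyntheticDataset, list[Bag]]:
    """Small-profile synthetic dataset tiled into per-case bags."""
    ds = generate_dataset(small_profile(n_cases=n_cases, seed=seed))
    cfg = ExtractionConfig(patch_size=patch_size)
    by_image = {im.image_id: extract_instances(im, cfg) for im in ds.images}
    return ds, build_bags(by_image, ds.manifest)


def run_mil_experiment(seed: int, regime: str = "admil", n_cases: int = 24,
                       epochs: int = 8, n_folds: int = 10,
                       backbone: str = "lenet_like",
                       dataset_and_bags=None) -> ExperimentResult:
    """Cross-validated MIL run on planted-signal synthetic data."""
    ds, bags = dataset_and_bags or build_synthetic_bags(n_cases, seed)
    splits = make_cv_splits(bags, n_folds=n_folds, seed=seed)
    config = TrainConfig(regime=regime, backbone=backbone, epochs=epochs, seed=seed)
    results, ckpts = run_cross_validation(bags, splits, config,
                                          return_checkpoints=True)
    rep = compute_metrics(results_to_confusion(results))
    logger.info("seed %d %s: balanced accuracy %.3f", seed, regime,
                rep.balanced_accuracy)
    return ExperimentResult(regime=regime, seed=seed,
                            balanced_accuracy=rep.balanced_accuracy,
                            accuracy=rep.accuracy, sensitivity=rep.sensitivity,
                            specificity=rep.specificity,
                            case_results=results, checkpoints=ckpts)


def attention_localization(ds: SyntheticDataset, bags: list[Bag],
                           result: ExperimentResult,
                           patch_size: int = 64) -> dict:
    """Do attention weights land on the planted malignant-like tiles?

    For every malignant bag the out-of-fold model classified correctly, each
    image's instance weights are normalised by that image's maximum and
    pooled into two groups: tiles containing a planted malignant-like cell
    center versus the remaining (background/benign) retained tiles.  Returns
    the two pooled means, their gap, and the fraction of bags whose own gap
    is positive.
    """
    if result.regime != "admil":
        raise ValueError("attention localization requires an admil experiment")
    by_id = {b.case_id: b for b in bags}
    fold_of = {r.case_id: r.fold for r in result.case_results}
    shapes = {im.image_id: im.pixels.shape[:2] for im in ds.images}

    planted, background, bag_gaps = [], [], []
    for r in result.case_results:
        if r.true_label != 1 or r.probability < 0.5:
            continue
        bag = by_id[r.case_id]
        model = result.checkpoints[fold_of[r.case_id]].build()
        pred = predict_bag(model, bag)
        per_image_max: dict[str, float] = {}
        for inst, a in zip(bag.instances, pred.attention_weights):
            m = per_image_max.get(inst.source_image_id, 0.0)
            per_image_max[inst.source_image_id] = max(m, float(a))
        bp, bb = [], []
        gt_grids = {img: ds.ground_truth.patch_labels(img, shapes[img], patch_size)
                    for img in per_image_max}
        for inst, a in zip(bag.instances, pred.attention_weights):
            norm = float(a) / per_image_max[inst.source_image_id]
            if gt_grids[inst.source_image_id][inst.grid_row, inst.grid_col]:
                bp.append(norm)
            else:
                bb.append(norm)
        planted.extend(bp)
        background.extend(bb)
        if bp and bb:
            bag_gaps.append(np.mean(bp) - np.mean(bb))
    mean_planted = float(np.mean(planted)) if planted else float("nan")
    mean_background = float(np.mean(background)) if background else float("nan")
    return {
        "mean_planted": mean_planted,
        "mean_background": mean_background,
        "gap": mean_planted - mean_background,
        "n_bags": len(bag_gaps),
        "fraction_bags_positive": (float(np.mean([g > 0 for g in bag_gaps]))
                                   if bag_gaps else float("nan")),
    }
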