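"""Training loops and cross-validated evaluation.

Three regimes are supported:

* ``admil``     — attention-pooled MIL, one bag per optimisation step;
* ``mean_mil``  — the conventional-MIL baseline (mean pooling), same loop;
* ``supervised``— per-instance learning where every patch inherits its case's
  weak label (deliberately noisy supervision), softmax head, batch 16; at
  evaluation a case's probability is the max over all its patches.

Model selection is by minimum validation loss across the epoch budget.  All
shuffling and weight initialisation derive from the config seed, so a run is
exactly replayable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bags import Bag, CVSplit
from .model import (BackboneSpec, BagPrediction, Checkpoint, DEFAULT_D,
                    DEFAULT_L, SupervisedModel, build_model, get_state)

logger = logging.getLogger(__name__)

F32 = np.float32

REGIMES = ("admil", "mean_mil", "supervised")


@dataclass(frozen=True)
class TrainConfig:
    regime: str = "admil"
    backbone: str = "lenet_like"
    epochs: int = 100
    batch_size: int | None = None          # None -> 1 for MIL, 16 for supervised
    learning_rate: float | None = None     # None -> 5e-4 for MIL, 5e-5 for supervised
    beta1: float = 0.9
    beta2: float = 0.999
    feature_dim: int = DEFAULT_L
    attention_dim: int = DEFAULT_D
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime in ("admil", "mean_mil") and self.batch_size not in (None, 1):
            raise ValueError("MIL regimes train one bag per step (batch_size 1)")

    @property
    def effective_batch_size(self) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return 1 if self.regime in ("admil", "mean_mil") else 16

    @property
    def effective_lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 5e-4 if self.regime in ("admil", "mean_mil") else 5e-5


@dataclass
class CaseResult:
    case_id: str
    true_label: int
    probability: float
    regime: str
    fold: int = -1

    @property
    def predicted_label(self) -> int:
        return 1 if self.probability >= 0.5 else 0


def bag_to_array(bag: Bag, input_size: int) -> np.ndarray:
    """Stack a bag's instances into (K, 3, S, S) float32 scaled to [0, 1]."""
    x = np.stack([i.pixels for i in bag.instances]).astype(F32) / F32(255.0)
    x = x.transpose(0, 3, 1, 2)
    if x.shape[2] != input_size or x.shape[3] != input_size:
        raise ValueError(f"bag {bag.case_id}: patch size {x.shape[2]} does not match "
                         f"model input size {input_size}")
    return np.ascontiguousarray(x)


def _bce(logit: float, y: float) -> float:
    # numerically stable binary cross-entropy on the logit
    return max(logit, 0.0) - logit * y + np.log1p(np.exp(-abs(logit)))


def _check_two_classes(labels: Sequence[int], what: str) -> None:
    if len(set(labels)) < 2:
        raise ValueError(f"{what} contains a single class; training is degenerate")


def predict_bag(model, bag: Bag) -> BagPrediction:
    x = bag_to_array(bag, model.spec.input_size)
    p, a, _ = model.forward_bag(x)
    return BagPrediction(case_id=bag.case_id, probability=p, attention_weights=a)


def _adam(model, config: TrainConfig):
    from .nn import Adam
    return Adam(model.params(), lr=config.effective_lr,
                beta1=config.beta1, beta2=config.beta2)


def train_mil(train_bags: list[Bag], val_bags: list[Bag],
              config: TrainConfig) -> Checkpoint:
    """Train an AD MIL or mean-pool MIL model; returns the best-validation checkpoint."""
    if config.regime not in ("admil", "mean_mil"):
        raise ValueError(f"train_mil cannot train regime {config.regime!r}")
    if not train_bags or not val_bags:
        raise ValueError("train and validation bag lists must be non-empty")
    _check_two_classes([b.label for b in train_bags], "training set")

    input_size = train_bags[0].instances[0].pixels.shape[0]
    spec = BackboneSpec(config.backbone, input_size=input_size,
                        feature_dim=config.feature_dim)
    model = build_model(config.regime, spec, seed=config.seed, D=config.attention_dim)
    opt = _adam(model, config)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    xs = {b.case_id: bag_to_array(b, input_size) for b in train_bags + val_bags}
    history: list[dict] = []
    best = (np.inf, -1, None)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(train_bags))
        tr_loss = 0.0
        for i in order:
            bag = train_bags[i]
            p, _, logit = model.forward_bag(xs[bag.case_id], train=True)
            tr_loss += _bce(logit, bag.label)
            model.backward_bag(p, bag.label)
            opt.step()
        va_loss = 0.0
        for bag in val_bags:
            _, _, logit = model.forward_bag(xs[bag.case_id])
            va_loss += _bce(logit, bag.label)
        tr_loss /= len(train_bags)
        va_loss /= len(val_bags)
        history.append({"epoch": epoch, "train_loss": tr_loss, "val_loss": va_loss})
        if va_loss < best[0]:
            best = (va_loss, epoch, get_state(model))
    state = best[2] if best[2] is not None else get_state(model)
    logger.info("%s/%s: best val loss %.4f at epoch %d", config.regime,
                config.backbone, best[0], best[1])
    return Checkpoint(regime=config.regime, backbone=config.backbone,
                      input_size=input_size, feature_dim=config.feature_dim,
                      attention_dim=config.attention_dim if config.regime == "admil" else None,
                      patch_size=input_size, state=state, history=history)


@dataclass
class PatchSet:
    """Flattened per-patch training data for the supervised baseline."""

    X: np.ndarray                 # (N, 3, S, S) float32 in [0, 1]
    y: np.ndarray                 # (N,) int, the broadcast case label
    image_ids: list[str]
    case_ids: list[str]

    @classmethod
    def from_bags(cls, bags: list[Bag], input_size: int) -> "PatchSet":
        xs, ys, imgs, cases = [], [], [], []
        for b in bags:
            xs.append(bag_to_array(b, input_size))
            ys.extend([b.label] * b.K)
            imgs.extend(i.source_image_id for i in b.instances)
            cases.extend([b.case_id] * b.K)
        return cls(X=np.concatenate(xs), y=np.array(ys, dtype=np.int64),
                   image_ids=imgs, case_ids=cases)


def train_supervised(train: PatchSet, val: PatchSet, config: TrainConfig) -> Checkpoint:
    """Train the per-instance softmax baseline (weak labels broadcast to patches)."""
    if config.regime != "supervised":
        raise ValueError(f"train_supervised cannot train regime {config.regime!r}")
    _check_two_classes(train.y.tolist(), "training set")
    input_size = train.X.shape[2]
    spec = BackboneSpec(config.backbone, input_size=input_size,
                        feature_dim=config.feature_dim)
    model = SupervisedModel(spec, seed=config.seed)
    opt = _adam(model, config)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    bs = config.effective_batch_size

    history: list[dict] = []
    best = (np.inf, -1, None)
    n = train.X.shape[0]
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        tr_loss = 0.0
        for s in range(0, n, bs):
            idx = order[s:s + bs]
            probs = model.forward_batch(train.X[idx], train=True)
            tr_loss -= float(np.log(probs[np.arange(len(idx)), train.y[idx]]
                                    + 1e-12).sum())
            model.backward_batch(probs, train.y[idx])
            opt.step()
        probs = model.forward_batch(val.X)
        va_loss = -float(np.log(probs[np.arange(val.X.shape[0]), val.y]
                                + 1e-12).mean())
        tr_loss /= n
        history.append({"epoch": epoch, "train_loss": tr_loss, "val_loss": va_loss})
        if va_loss < best[0]:
            best = (va_loss, epoch, get_state(model))
    state = best[2] if best[2] is not None else get_state(model)
    return Checkpoint(regime="supervised", backbone=config.backbone,
                      input_size=input_size, feature_dim=config.feature_dim,
                      attention_dim=None, patch_size=input_size,
                      state=state, history=history)


def case_max_aggregate(probabilities: Sequence[float]) -> float:
    """Case probability = max over per-image malignancy probabilities."""
    probabilities = list(probabilities)
    if not probabilities:
        raise ValueError("case_max_aggregate requires at least one probability")
    return float(max(probabilities))


def _predict_supervised_case(model: SupervisedModel, bag: Bag) -> float:
    x = bag_to_array(bag, model.spec.input_size)
    probs = model.forward_batch(x)[:, 1]
    per_image: dict[str, float] = {}
    for inst, p in zip(bag.instances, probs):
        per_image[inst.source_image_id] = max(
            per_image.get(inst.source_image_id, 0.0), float(p))
    return case_max_aggregate(list(per_image.values()))


def run_cross_validation(bags: list[Bag], splits: CVSplit, config: TrainConfig,
                         return_checkpoints: bool = False):
    """Out-of-fold prediction for every case; optionally the fold checkpoints.

    The per-fold models are trained on the fold's train cases (validation
    slice held out for model selection) and applied to its test cases; the
    concatenated results form one confusion matrix over all cases.
    """
    by_id = {b.case_id: b for b in bags}
    covered = {c for f in splits.folds for c in f.test}
    if covered != set(by_id):
        raise ValueError("splits do not cover the bag set exactly")

    results: list[CaseResult] = []
    checkpoints: list[Checkpoint] = []
    for k, fold in enumerate(splits.folds):
        overlap = set(fold.test) & (set(fold.train) | set(fold.val))
        if overlap:  # leakage guard: split must be by case
            raise AssertionError(f"fold {k}: cases {sorted(overlap)} leak into training")
        train_bags = [by_id[c] for c in fold.train]
        val_bags = [by_id[c] for c in fold.val]
        test_bags = [by_id[c] for c in fold.test]
        fold_config = TrainConfig(**{**config.__dict__, "seed": config.seed + 1000 * k})
        if config.regime == "supervised":
            size = train_bags[0].instances[0].pixels.shape[0]
            ckpt = train_supervised(PatchSet.from_bags(train_bags, size),
                                    PatchSet.from_bags(val_bags, size), fold_config)
            model = ckpt.build()
            for bag in test_bags:
                p = _predict_supervised_case(model, bag)
                results.append(CaseResult(bag.case_id, bag.label, p,
                                          config.regime, fold=k))
        else:
            ckpt = train_mil(train_bags, val_bags, fold_config)
            model = ckpt.build()
            for bag in test_bags:
                pred = predict_bag(model, bag)
                results.append(CaseResult(bag.case_id, bag.label, pred.probability,
                                          config.regime, fold=k))
        checkpoints.append(ckpt)
        logger.info("fold %d/%d done (%s)", k + 1, splits.n_folds, config.regime)
    results.sort(key=lambda r: r.case_id)
    if return_checkpoints:
        return results, checkpoints
    return results
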