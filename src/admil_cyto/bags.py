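"""Per-case bag assembly and case-stratified cross-validation splits.

The unit of classification is the case: all retained patches from all of a
case's images form one bag carrying a single weak label.  Splits are always
by case — never by image or patch — so no pixels from a test case can reach
training, and folds are stratified by label because benign prevalence is
well below one half in the motivating data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .extraction import PatchInstance

logger = logging.getLogger(__name__)

LABEL_TO_INT = {"benign": 0, "malignant": 1}


class ManifestError(ValueError):
    """Instance manifest references an image or case the case manifest lacks."""


@dataclass
class Bag:
    case_id: str
    label: int  # 0 = benign, 1 = malignant
    instances: list[PatchInstance]

    @property
    def K(self) -> int:
        return len(self.instances)


def build_bags(instances_by_image: dict[str, list[PatchInstance]],
               manifest: pd.DataFrame) -> list[Bag]:
    """Group retained instances into one bag per case.

    Instances are ordered by (image_id, grid_row, grid_col); cases whose
    every image was filtered to nothing are excluded with a warning (a bag
    must hold at least one instance to be classified).
    """
    image_case = dict(zip((Path(p).stem for p in manifest["image_path"]),
                          manifest["case_id"].astype(str)))
    case_label = dict(zip(manifest["case_id"].astype(str), manifest["label"]))
    per_case: dict[str, list[PatchInstance]] = {c: [] for c in case_label}
    for image_id, instances in instances_by_image.items():
        if image_id not in image_case:
            raise ManifestError(f"image {image_id!r} is not in the case manifest")
        per_case[image_case[image_id]].extend(instances)

    bags = []
    for case_id, label in case_label.items():
        inst = sorted(per_case[case_id],
                      key=lambda i: (i.source_image_id, i.grid_row, i.grid_col))
        if not inst:
            logger.warning("case %s has no retained instances; excluded", case_id)
            continue
        bags.append(Bag(case_id=case_id, label=LABEL_TO_INT[label], instances=inst))
    return bags


@dataclass
class FoldSplit:
    train: list[str]
    val: list[str]
    test: list[str]


@dataclass
class CVSplit:
    n_folds: int
    seed: int
    folds: list[FoldSplit] = field(default_factory=list)

    def fold_of(self) -> dict[str, int]:
        return {c: k for k, f in enumerate(self.folds) for c in f.test}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "n_folds": self.n_folds, "seed": self.seed,
            "folds": [{"train": f.train, "val": f.val, "test": f.test}
                      for f in self.folds]}))

    @classmethod
    def from_json(cls, path) -> "CVSplit":
        d = json.loads(Path(path).read_text())
        return cls(n_folds=d["n_folds"], seed=d["seed"],
                   folds=[FoldSplit(**f) for f in d["folds"]])


def make_cv_splits(bags: list[Bag], n_folds: int = 10, seed: int = 0,
                   val_fraction: float = 0.1) -> CVSplit:
    """Case-stratified k-fold split with a held-out validation slice per fold.

    Each fold's training cases additionally cede ``val_fraction`` (stratified,
    at least one case) to validation for model selection.
    """
    if n_folds > len(bags):
        raise ValueError(f"n_folds={n_folds} exceeds the {len(bags)} available bags")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    case_ids = np.array([b.case_id for b in bags])
    labels = np.array([b.label for b in bags])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    split = CVSplit(n_folds=n_folds, seed=seed)
    for k, (train_idx, test_idx) in enumerate(skf.split(case_ids, labels)):
        tr_cases, tr_labels = case_ids[train_idx], labels[train_idx]
        n_val = max(1, round(val_fraction * len(tr_cases)))
        if n_val >= 2 and min(np.bincount(tr_labels, minlength=2)) >= 2:
            tr, va = train_test_split(tr_cases, test_size=n_val,
                                      random_state=seed + k, stratify=tr_labels)
        else:
            # too few cases to stratify: seeded draw that keeps both labels in train
            rng = np.random.default_rng(seed + k)
            order = rng.permutation(len(tr_cases))
            va_idx, tr_idx = list(order[:n_val]), list(order[n_val:])
            for li, lab in enumerate(sorted(set(tr_labels))):
                if not any(tr_labels[i] == lab for i in tr_idx):
                    swap = next(i for i in va_idx if tr_labels[i] == lab)
                    give = tr_idx.pop()
                    tr_idx.append(swap)
                    va_idx[va_idx.index(swap)] = give
            tr, va = tr_cases[tr_idx], tr_cases[va_idx]
        split.folds.append(FoldSplit(train=sorted(tr), val=sorted(va),
                                     test=sorted(case_ids[test_idx])))
    return split
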