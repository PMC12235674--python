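"""Cross-platform stratified 75/25 partitioning and 10-fold CV assignment.

Training samples are drawn per class, floor(frac * n_c) without replacement,
from the training platform; the test set is every sample of the other
platform whose ID does not appear in training.  Fold assignment is stratified
round-robin dealing after a seeded within-class shuffle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from crossnorm.core_io import DataError, SubtypeLabels


@dataclass
class PartitionPlan:
    repeat_index: int
    train_sample_ids: list[str]
    test_sample_ids: list[str]
    fold_of: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.train_sample_ids) & set(self.test_sample_ids):
            raise DataError("train and test sample ID sets overlap")

    def to_dict(self) -> dict:
        return {
            "repeat_index": self.repeat_index,
            "seed": self.seed,
            "train_sample_ids": list(self.train_sample_ids),
            "test_sample_ids": list(self.test_sample_ids),
            "fold_of": dict(self.fold_of),
        }


def split_cross_platform(
    train_labels: SubtypeLabels,
    other_platform_ids,
    frac: float = 0.75,
    seed: int = 0,
    repeat_index: int = 0,
) -> PartitionPlan:
    """Stratified draw of floor(frac*n_c) per class; test = other platform minus train IDs.

    A class small enough that floor(frac*n_c) = 0 is left out of training with
    a warning (not an error), mirroring heavily imbalanced cohorts.
    """
    if not (0 < frac < 1):
        raise DataError(f"frac must be in (0,1), got {frac}")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    idx = train_labels.labels.index
    for cls in train_labels.class_order:
        members = list(idx[train_labels.labels == cls])
        if not members:
            continue
        m = int(np.floor(frac * len(members)))
        if m == 0:
            warnings.warn(f"class {cls!r} too small for training (n={len(members)})", stacklevel=2)
            continue
        train_ids.extend(rng.choice(members, size=m, replace=False).tolist())
    train_set = set(train_ids)
    test_ids = [s for s in other_platform_ids if s not in train_set]
    return PartitionPlan(repeat_index, train_ids, test_ids, seed=seed)


def assign_folds(
    plan: PartitionPlan, labels: SubtypeLabels, k: int = 10, seed: int | None = None
) -> PartitionPlan:
    """Stratified fold assignment: per class, seeded shuffle then round-robin deal."""
    if k < 2:
        raise DataError("k must be >= 2")
    if k > len(plan.train_sample_ids):
        raise DataError(f"k={k} exceeds training size {len(plan.train_sample_ids)}")
    rng = np.random.default_rng(plan.seed + 1 if seed is None else seed)
    y = labels.y(plan.train_sample_ids)
    fold_of: dict[str, int] = {}
    for cls in labels.class_order:
        members = [s for s, c in zip(plan.train_sample_ids, y) if c == cls]
        rng.shuffle(members)
        for pos, s in enumerate(members):
            fold_of[s] = pos % k
    plan.fold_of = fold_of
    return plan


def make_repeats(
    train_labels: SubtypeLabels,
    other_platform_ids,
    frac: float = 0.75,
    k: int = 10,
    n_repeats: int = 5,
    base_seed: int = 0,
) -> list[PartitionPlan]:
    """Independent re-partitions with per-repeat seeds base_seed + index."""
    plans = []
    for i in range(n_repeats):
        plan = split_cross_platform(
            train_labels, other_platform_ids, frac=frac, seed=base_seed + i, repeat_index=i
        )
        plans.append(assign_folds(plan, train_labels, k=k))
    return plans
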