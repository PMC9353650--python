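"""Stratified dataset splitting for semi-supervised training.

The protocol: a class-stratified train/validation/test split in the ratio
7:1:2, after which the training portion is further split 8:2 into a
labeled subset and an "unlabeled" subset whose labels are hidden from the
trainer (but retained for audit).  Per class the split sizes follow
largest-remainder apportionment of ratio * n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DatasetSplit", "split_ssl", "stratified_split"]


@dataclass
class DatasetSplit:
    """Index lists into the original dataset for every split."""
    train_labeled: np.ndarray
    train_unlabeled: np.ndarray
    val: np.ndarray
    test: np.ndarray
    hidden_labels: np.ndarray = field(default=None)  # audit copy for train_unlabeled

    def all_disjoint(self) -> bool:
        parts = [self.train_labeled, self.train_unlabeled, self.val, self.test]
        cat = np.concatenate(parts)
        return len(cat) == len(set(cat.tolist()))


def _apportion(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n samples to the ratio parts.

    Each part gets floor(n * ratio); leftover units go to the parts with
    the largest fractional remainders.  Every part size is within one
    sample of n * ratio, so stratified splits track the class proportions.
    A 546-sample training set under an 8:2 labeled/unlabeled split (two
    balanced classes of 273) gives 436 labeled / 110 unlabeled.
    """
    exact = [n * r for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    leftovers = np.argsort([s - e for s, e in zip(sizes, exact)])
    for i in leftovers[:n - sum(sizes)]:
        sizes[i] += 1
    return sizes


def stratified_split(labels: np.ndarray, ratios: tuple[float, ...],
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle within each class and cut into len(ratios) parts."""
    labels = np.asarray(labels)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    parts: list[list[int]] = [[] for _ in ratios]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < len(ratios):
            raise ValueError(
                f"class {c} has {len(idx)} samples, fewer than the "
                f"{len(ratios)} splits")
        idx = rng.permutation(idx)
        sizes = _apportion(len(idx), ratios)
        start = 0
        for i, s in enumerate(sizes):
            parts[i].extend(idx[start:start + s].tolist())
            start += s
    return [np.sort(np.asarray(p, dtype=np.intp)) for p in parts]


def split_ssl(labels: np.ndarray,
              tvt_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
              labeled_fraction: float = 0.8,
              seed: int = 0) -> DatasetSplit:
    """Stratified 7:1:2 train/val/test split, then 8:2 labeled/unlabeled.

    Reproducible given the seed.  The unlabeled subset's labels are kept
    only in ``hidden_labels`` for later audit; the trainer never sees them.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    train, val, test = stratified_split(labels, tvt_ratios, rng)
    lab, unlab = stratified_split(
        labels[train], (labeled_fraction, 1.0 - labeled_fraction), rng)
    return DatasetSplit(
        train_labeled=train[lab],
        train_unlabeled=train[unlab],
        val=val,
        test=test,
        hidden_labels=labels[train[unlab]].copy(),
    )
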