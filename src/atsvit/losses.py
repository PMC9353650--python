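"""The three training losses and their aggregation.

Supervised branch: one-vs-all binary cross-entropy with logits against
one-hot targets (reduces to ordinary BCE for two classes; prediction is
argmax over the per-class sigmoids).

Consistency branch, for an unlabeled image x and its augmented version z:

* pseudo-label loss — mean squared distance between the class-probability
  vectors F(x) and F(z), with F(x) treated as a fixed pseudo-label
  (no gradient through the clean branch);
* Earth Mover's loss — the minimum total squared-Euclidean cost over all
  one-to-one matchings between the two final-block token sequences,
  computed exactly by optimal assignment on the pairwise cost matrix.

The total objective is the unweighted sum of the three components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .autodiff import Tensor

__all__ = ["LossBundle", "supervised_loss", "pseudo_label_loss", "em_loss",
           "total_loss"]


@dataclass(frozen=True)
class LossBundle:
    """The three loss components and their sum (floats for logging)."""
    ce: float
    mse: float
    em: float

    @property
    def total(self) -> float:
        return self.ce + self.mse + self.em


def supervised_loss(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean element-wise BCE-with-logits against one-hot targets."""
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim == 2:
        row_sums = targets.sum(axis=1)
        if not np.allclose(row_sums, 1.0):
            raise ValueError("one-hot target rows must sum to 1")
    return logits.bce_with_logits(targets)


def pseudo_label_loss(probs_clean: np.ndarray, probs_aug: Tensor) -> Tensor:
    """(1/m) sum_u ||F(x_u) - F(z_u)||^2 with a stop-gradient pseudo-label.

    ``probs_clean`` is the detached probability matrix of the unperturbed
    images; ``probs_aug`` the (differentiable) probabilities of the
    augmented images.
    """
    probs_clean = np.asarray(probs_clean, dtype=np.float64)
    if probs_clean.shape != probs_aug.shape:
        raise ValueError(
            f"unpaired batches: {probs_clean.shape} vs {probs_aug.shape}")
    m = probs_clean.shape[0] if probs_clean.ndim > 1 else 1
    diff = probs_aug - Tensor(probs_clean)
    return (diff * diff).sum() / m


def em_loss(p: Tensor | np.ndarray, q: Tensor | np.ndarray) -> Tensor:
    """Earth Mover's discrepancy between two token sequences.

    For equal-length sequences this is the exact minimum over all
    permutations pi of sum_i ||q_pi(i) - p_i||^2, found in polynomial time
    by optimal assignment (provably equal to the permutation minimum) and
    divided by the sequence length so the value is length-invariant.  If
    the sequences differ in length, every token of the shorter one is
    matched to a distinct token of the longer (partial matching),
    normalized by the matched count.

    Symmetric, invariant to reordering of either sequence, and zero iff a
    perfect matching exists.
    """
    pt = p if isinstance(p, Tensor) else Tensor(p)
    qt = q if isinstance(q, Tensor) else Tensor(q)
    if pt.data.ndim != 2 or qt.data.ndim != 2:
        raise ValueError("token sequences must be 2-D (tokens x dim)")
    if pt.data.shape[1] != qt.data.shape[1]:
        raise ValueError(
            f"token dimension mismatch: {pt.data.shape[1]} vs {qt.data.shape[1]}")
    # pairwise squared Euclidean costs, on detached data
    d2 = ((pt.data[:, None, :] - qt.data[None, :, :]) ** 2).sum(axis=-1)
    rows, cols = linear_sum_assignment(d2)
    m = len(rows)
    diff = pt.gather_rows(rows) - qt.gather_rows(cols)
    return (diff * diff).sum() / m


def total_loss(ce: Tensor | None, mse: Tensor | None, em: Tensor | None,
               weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
               ) -> tuple[Tensor, LossBundle]:
    """Aggregate the components: L = L_CE + L_MSE + L_EM.

    Missing components (e.g. no unlabeled batch) count as zero.  Returns
    the differentiable total and a float bundle for logging.
    """
    parts = {"ce": ce, "mse": mse, "em": em}
    vals = {}
    for name, part in parts.items():
        if part is not None and not np.isfinite(part.data):
            raise FloatingPointError(f"non-finite loss component: {name}")
        vals[name] = float(part.data) if part is not None else 0.0
    total = None
    for w, part in zip(weights, (ce, mse, em)):
        if part is None:
            continue
        term = part * w
        total = term if total is None else total + term
    if total is None:
        raise ValueError("at least one loss component is required")
    bundle = LossBundle(ce=vals["ce"] * weights[0], mse=vals["mse"] * weights[1],
                        em=vals["em"] * weights[2])
    return total, bundle
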