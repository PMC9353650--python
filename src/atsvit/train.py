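"""End-to-end semi-supervised training loop.

Each optimization step draws one labeled batch and one unlabeled batch
(the unlabeled loader cycles when exhausted).  The labeled batch is
forwarded for the supervised BCE loss; the unlabeled images and their
augmented versions are forwarded through the *same* model (shared
parameters) for the pseudo-label MSE and the Earth Mover's token loss.
One Adam step is taken on the unweighted sum of the three components.

Consistency forward passes use deterministic-quantile token sampling so
the clean and augmented token sequences are reproducible and (almost
always) of matching length; the labeled branch samples stochastically,
which regularizes like dropout.  Checkpoint selection is by validation
macro-F1 under deterministic sampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .augment import AugmentationSet, default_augmentations
from .autodiff import Adam
from .losses import LossBundle, em_loss, pseudo_label_loss, supervised_loss, total_loss
from .metrics import MetricsReport, evaluate
from .model import ViTATS

__all__ = ["TrainConfig", "EpochRecord", "TrainResult", "train", "one_hot"]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the reference training setting for the full-scale
    model: Adam with learning rate 2e-5 and eps 1e-8, batch size 64,
    300 epochs, 256 x 256 inputs, token schedule (256, 128, 64, 32, 16, 8).
    Desk-scale experiments override these.
    """
    learning_rate: float = 2e-5
    eps: float = 1e-8
    batch_size: int = 64
    epochs: int = 300
    input_size: int = 256
    ats_tokens: tuple[int, ...] | None = (256, 128, 64, 32, 16, 8)
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    train_sampling: str = "stochastic"
    consistency_sampling: str = "deterministic"
    seed: int = 0


@dataclass
class EpochRecord:
    epoch: int
    ce: float
    mse: float
    em: float
    total: float
    val: MetricsReport | None = None

    def as_line(self) -> str:
        d = {"epoch": self.epoch, "L_CE": round(self.ce, 6),
             "L_MSE": round(self.mse, 6), "L_EM": round(self.em, 6),
             "L": round(self.total, 6)}
        if self.val is not None:
            d.update({f"val_{k}": v for k, v in self.val.as_percent().items()})
        return json.dumps(d)


@dataclass
class TrainResult:
    log: list[EpochRecord]
    step_bundles: list[LossBundle]
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_f1: float


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.intp)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def train(model: ViTATS, labeled_images, labeled_labels, unlabeled_images,
          config: TrainConfig, val_images=None, val_labels=None,
          augmentations: AugmentationSet | None = None,
          log_path=None) -> TrainResult:
    """Run the semi-supervised loop and return the log + best checkpoint.

    ``labeled_labels`` are integer class indices.  With an empty
    ``unlabeled_images`` the loop degrades to supervised-only training
    (a warning is logged and the consistency losses stay at zero).
    """
    cfg = config
    n_classes = model.config.num_classes
    rng = np.random.default_rng(cfg.seed)
    if augmentations is None:
        augmentations = default_augmentations(seed=cfg.seed + 1)
    labeled_images = list(labeled_images)
    labels = np.asarray(labeled_labels, dtype=np.intp)
    targets = one_hot(labels, n_classes)
    unlabeled_images = list(unlabeled_images)
    if not unlabeled_images:
        logger.warning("empty unlabeled set: training supervised-only")
    opt = Adam(model.parameters(), lr=cfg.learning_rate, eps=cfg.eps)

    n = len(labeled_images)
    u_order: list[int] = []
    records: list[EpochRecord] = []
    bundles: list[LossBundle] = []
    best_state = model.state_dict()
    best_f1, best_epoch = -1.0, -1
    log_fh = open(log_path, "w") if log_path is not None else None
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            ep_parts = np.zeros(4)
            n_steps = 0
            for start in range(0, n, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                x_l = [labeled_images[i] for i in batch]
                logits, _, _ = model.forward(x_l, mode=cfg.train_sampling, rng=rng)
                l_ce = supervised_loss(logits, targets[batch])
                l_mse = l_em = None
                if unlabeled_images:
                    m = len(batch)
                    while len(u_order) < m:  # cycle the unlabeled loader
                        u_order.extend(rng.permutation(len(unlabeled_images)).tolist())
                    u_batch = [u_order.pop(0) for _ in range(m)]
                    x_u = [unlabeled_images[i] for i in u_batch]
                    z_u = [augmentations.apply(x)[0] for x in x_u]
                    logits_x, tok_x, _ = model.forward(
                        x_u, mode=cfg.consistency_sampling)
                    logits_z, tok_z, _ = model.forward(
                        z_u, mode=cfg.consistency_sampling)
                    pseudo = logits_x.sigmoid().data  # stop-gradient pseudo-label
                    l_mse = pseudo_label_loss(pseudo, logits_z.sigmoid())
                    # lengths may rarely differ after deduplicated sampling;
                    # em_loss falls back to partial matching in that case
                    em_terms = [em_loss(a, b) for a, b in zip(tok_x, tok_z)]
                    l_em = em_terms[0]
                    for t in em_terms[1:]:
                        l_em = l_em + t
                    l_em = l_em / len(em_terms)
                loss, bundle = total_loss(l_ce, l_mse, l_em,
                                          weights=cfg.loss_weights)
                opt.zero_grad()
                loss.backward()
                opt.step()
                bundles.append(bundle)
                ep_parts += (bundle.ce, bundle.mse, bundle.em, bundle.total)
                n_steps += 1
            ep_parts /= max(n_steps, 1)
            val_report = None
            if val_images is not None and len(val_images):
                preds = model.predict(val_images)
                val_report = evaluate(val_labels, preds, n_classes)
                if val_report.f1 > best_f1:
                    best_f1 = val_report.f1
                    best_epoch = epoch
                    best_state = model.state_dict()
            rec = EpochRecord(epoch=epoch, ce=ep_parts[0], mse=ep_parts[1],
                              em=ep_parts[2], total=ep_parts[3], val=val_report)
            records.append(rec)
            if log_fh is not None:
                log_fh.write(rec.as_line() + "\n")
    finally:
        if log_fh is not None:
            log_fh.close()
    if best_epoch < 0:  # no validation set: keep the final parameters
        best_state = model.state_dict()
        best_epoch = cfg.epochs - 1
    return TrainResult(log=records, step_bundles=bundles,
                       best_state=best_state, best_epoch=best_epoch,
                       best_val_f1=best_f1)
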