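"""Training loop: softmax cross-entropy, Adadelta, and validation-based
epoch selection.

Optimization follows the published recipe: Adadelta at initial learning
rate 1.0, decayed exponentially by 0.95 every 3 epochs, batch size 128,
patches converted RGB -> HSV before entering the network.  Each training
patch receives one random dihedral orientation and one HSV/contrast jitter
draw per epoch.  After every epoch the validation patch AUC is computed and
the returned model carries the best-epoch weights ("the optimal number of
training epochs" is chosen on validation performance).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .augment import JitterProfile, color_jitter, dihedral_apply, rgb_to_hsv
from .model import Model
from .patch_sampler import PatchSet

log = logging.getLogger(__name__)

#: Published per-dataset epoch budgets.
EPOCH_PRESETS = {"scc": 30, "thyroid": 70, "lymph_node": 20}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    init_lr: float = 1.0
    decay: float = 0.95
    decay_every_epochs: int = 3
    max_epochs: int = 30
    jitter: JitterProfile = field(default_factory=JitterProfile)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError(f"decay {self.decay} outside (0, 1]")
        if self.decay_every_epochs < 1:
            raise ValueError("decay_every_epochs must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_auc: float
    lr: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1

    def column(self, name: str) -> list[float]:
        return [getattr(r, name) for r in self.records]

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_auc,lr\n")
            for r in self.records:
                fh.write(f"{r.epoch},{r.train_loss:.6f},{r.val_auc:.6f},{r.lr:.6f}\n")


# ------------------------------------------------------------- closed forms

def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate at a 0-based epoch index: init * decay^floor(epoch/k)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.init_lr * config.decay ** (epoch // config.decay_every_epochs)


def loss(predictions: np.ndarray, labels: np.ndarray, floor: float = 1e-12) -> float:
    """Mean two-class cross-entropy from per-patch probabilities.

    ``predictions`` is either an (N, 2) array of class probabilities
    (columns: cancer-negative, cancer-positive) or an (N,) array of
    cancer probabilities; ``labels`` is binary (1 = cancer) or one-hot.
    Log arguments are floored at ``floor``.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[:, 1]
    if predictions.ndim == 2:
        p_true = np.where(labels > 0, predictions[:, 1], predictions[:, 0])
    else:
        p_true = np.where(labels > 0, predictions, 1.0 - predictions)
    return float(-np.mean(np.log(np.maximum(p_true, floor))))


# ------------------------------------------------------------------ fitting

def _augment_batch(
    patches: PatchSet, idx: np.ndarray, jitter: JitterProfile, rng: np.random.Generator
) -> np.ndarray:
    """One random dihedral variant + jitter per patch, RGB -> HSV."""
    out = np.empty((len(idx),) + patches.pixels.shape[1:], dtype=np.float32)
    for row, i in enumerate(idx):
        k = int(rng.integers(0, 8))
        hsv = rgb_to_hsv(dihedral_apply(patches.pixels[i], k))
        out[row] = color_jitter(hsv, jitter, rng)
    return out


def fit(
    model: Model,
    train_patches: PatchSet,
    val_patches: PatchSet,
    config: TrainConfig,
) -> tuple[Model, TrainHistory]:
    """Train the classifier; returns the best-validation-AUC checkpoint.

    ``train_patches`` and ``val_patches`` hold RGB pixels; color conversion
    and augmentation happen per batch.  Fully seeded: identical inputs,
    config and seed give identical histories (single-threaded numpy).
    """
    from .evaluate import roc_auc
    from .infer import predict_patches

    if len(val_patches) == 0:
        raise ValueError("validation set is empty: epoch selection is undefined")
    if len(train_patches) == 0:
        raise ValueError("training set is empty")
    overlap = set(train_patches.slide_refs) & set(val_patches.slide_refs)
    if overlap:
        raise ValueError(f"slides present in both training and validation: {sorted(overlap)}")

    rng = np.random.default_rng(config.seed)
    opt = ad.Adadelta(model.parameters())
    labels = train_patches.labels.astype(np.int64)
    onehot_all = np.eye(2, dtype=np.float32)[labels]
    history = TrainHistory()
    best_auc, best_params = -np.inf, None

    for epoch in range(config.max_epochs):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(len(train_patches))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = _augment_batch(train_patches, idx, config.jitter, rng)
            opt.zero_grad()
            logits = model.logits(batch, train=True)
            batch_loss = ad.softmax_cross_entropy(logits, onehot_all[idx])
            batch_loss.backward()
            opt.step(lr)
            losses.append(float(batch_loss.data))
        val_scores = predict_patches(model, val_patches)
        val_auc = roc_auc(val_scores, val_patches.labels)
        history.records.append(EpochRecord(epoch, float(np.mean(losses)), val_auc, lr))
        log.info("epoch %d: loss %.4f, val AUC %.4f, lr %.4f", epoch, np.mean(losses), val_auc, lr)
        if val_auc > best_auc:
            best_auc = val_auc
            history.best_epoch = epoch
            best_params = [p.data.copy() for p in model.parameters()]

    if best_params is not None:
        for p, data in zip(model.parameters(), best_params):
            p.data = data
    return model, copy.deepcopy(history)
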