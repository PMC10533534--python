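"""Training loop with class-balanced batches and few-shot outlier
exposure.

Conventions: batches are class-balanced over the inlier classes by
weighted sampling; when outlier exposure is active, roughly half of the
batches (Bernoulli with ``batch_prob``) carry between 1 and N outlier
images, N = min(batch_size // (K + 1), available outliers) — the
balanced share a (K+1)-th class would get. The exposed outliers are a
small fixed subset of the exposure pool selected by the replicate index;
disjoint replicates see disjoint subsets. The loss on exposed outliers
depends on the head: an extra abstention class for the reject-bucket
head, a uniform-target entropy regularizer otherwise.

The optimizer is SGD (optional momentum) with learning-rate reduction on
a validation-loss plateau and early stopping; the best-validation
weights are restored at the end. Everything is deterministic in
``TrainConfig.seed``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_batch
from .losses import (ce_grad_logits, dirichlet_grad_logits,
                     dirichlet_uniform_ce_grad_logits, loss_ce,
                     uniform_ce_grad_logits)
from .nets import CompactNet
from .synthgen import INLIER_CLASSES, ImageSet

__all__ = ["TrainConfig", "ExposureConfig", "ExposureBatchSampler",
           "select_exposure_subset", "train"]


@dataclass
class TrainConfig:
    """Optimization settings.

    The defaults keep the original fine-tuning conventions (batch 32,
    SGD, initial learning rate 1e-4 with plateau reduction by 0.1 down
    to 1e-8, patience 5, up to 100 epochs, early stop patience 15, and
    the full augmentation recipe). :meth:`desk_scale` returns the preset
    retuned for the small dense backbone shipped with this package —
    see docs/methods.md.
    """

    batch_size: int = 32
    learning_rate: float = 1e-4
    momentum: float = 0.0
    lr_factor: float = 0.1
    lr_floor: float = 1e-8
    lr_patience: int = 5
    max_epochs: int = 100
    early_stop_patience: int = 15
    oe_lambda: float = 0.1
    kl_anneal_epochs: int = 10
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "TrainConfig":
        cfg = cls(learning_rate=0.02, momentum=0.9, max_epochs=80,
                  early_stop_patience=12, lr_patience=6, seed=seed)
        return replace(cfg, **overrides)


@dataclass
class ExposureConfig:
    """Few-shot outlier-exposure settings.

    ``n_per_class`` unique outlier subjects per exposed class are drawn
    from the exposure pool; ``replicate`` indexes disjoint subsets so
    repeated experiments see different outliers. ``n_per_class = 0``
    disables exposure entirely.
    """

    classes: tuple[str, ...] = ("DME", "RVO", "Stargardt")
    n_per_class: int = 0
    batch_prob: float = 0.5
    replicate: int = 0

    def validate(self) -> None:
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if not 0.0 <= self.batch_prob <= 1.0:
            raise ValueError("batch_prob must lie in [0, 1]")
        if self.replicate < 0:
            raise ValueError("replicate must be >= 0")
        if not self.classes:
            raise ValueError("at least one exposed class is required")


def select_exposure_subset(pool: ImageSet, exposure: ExposureConfig,
                           seed: int = 0) -> ImageSet:
    """Pick the exposed outlier images for one replicate.

    Subjects of each exposed class are shuffled once (seed-controlled,
    independent of the replicate index) and replicate ``r`` takes the
    r-th block of ``n_per_class`` subjects, so subsets of different
    replicates are disjoint.
    """
    exposure.validate()
    if exposure.n_per_class == 0:
        raise ValueError("exposure requested with n_per_class = 0")
    picks = []
    for cls in exposure.classes:
        cls_set = pool.by_label(cls)
        subjects = np.array(sorted(set(cls_set.subject_ids)))
        if len(subjects) == 0:
            raise ValueError(f"exposure pool has no subjects of class {cls!r}")
        cls_key = zlib.crc32(cls.encode()) % 2**31
        rng = np.random.default_rng(np.random.SeedSequence([seed, cls_key]))
        order = rng.permutation(len(subjects))
        lo = exposure.replicate * exposure.n_per_class
        hi = lo + exposure.n_per_class
        if hi > len(subjects):
            raise ValueError(
                f"replicate {exposure.replicate} with n={exposure.n_per_class} "
                f"exceeds the {len(subjects)} pool subjects of class {cls!r}")
        chosen = set(subjects[order[lo:hi]])
        picks.append(cls_set.select(np.isin(cls_set.subject_ids, list(chosen))))
    return ImageSet.concatenate(picks)


class ExposureBatchSampler:
    """Class-balanced batch sampler with stochastic outlier exposure."""

    def __init__(self, train_inliers: ImageSet, batch_size: int = 32,
                 outliers: ImageSet | None = None, batch_prob: float = 0.5,
                 classes: tuple[str, ...] = INLIER_CLASSES):
        self.classes = tuple(c for c in classes if np.any(train_inliers.labels == c))
        if len(self.classes) < 2:
            raise ValueError("need at least two inlier classes with samples")
        for c in classes:
            if c not in self.classes:
                raise ValueError(f"inlier class {c!r} has no training samples")
        self.batch_size = batch_size
        self.batch_prob = batch_prob
        self.inliers = train_inliers
        self.by_class = {c: np.flatnonzero(train_inliers.labels == c)
                         for c in self.classes}
        self.outliers = outliers if outliers is not None and len(outliers) else None
        K = len(self.classes)
        self.cap = (min(batch_size // (K + 1), len(self.outliers))
                    if self.outliers is not None else 0)

    @property
    def outlier_subjects(self) -> set[str]:
        return set(self.outliers.subject_ids) if self.outliers is not None else set()

    def next_batch(self, rng: np.random.Generator):
        """Returns (pixels, labels, is_outlier) for one batch. ``labels``
        are inlier class indices; outlier rows carry ``-1``."""
        n_out = 0
        if self.outliers is not None and self.cap > 0 and rng.random() < self.batch_prob:
            n_out = int(rng.integers(1, self.cap + 1))
        n_in = self.batch_size - n_out
        cls_draw = rng.integers(0, len(self.classes), size=n_in)
        idx = np.array([rng.choice(self.by_class[self.classes[c]]) for c in cls_draw])
        X = self.inliers.pixels[idx]
        y = cls_draw.astype(int)
        flag = np.zeros(self.batch_size, dtype=bool)
        if n_out:
            oidx = rng.choice(len(self.outliers), size=n_out, replace=False)
            X = np.concatenate([X, self.outliers.pixels[oidx]])
            y = np.concatenate([y, np.full(n_out, -1, dtype=int)])
            flag[n_in:] = True
        return X, y, flag


def _batch_loss_grad(model: CompactNet, logits: np.ndarray, y: np.ndarray,
                     is_out: np.ndarray, cfg: TrainConfig, annealing: float):
    """Assemble (loss, dlogits) for one mixed inlier/outlier batch."""
    dlogits = np.zeros_like(logits)
    n_in = int((~is_out).sum())
    n_out = int(is_out.sum())

    if model.head == "reject_bucket":
        labels = np.where(is_out, model.K, y)
        return ce_grad_logits(logits, labels)

    if model.head == "dirichlet":
        loss, d = dirichlet_grad_logits(logits[~is_out], y[~is_out], annealing)
        dlogits[~is_out] = d
        if n_out:
            reg, dreg = dirichlet_uniform_ce_grad_logits(logits[is_out],
                                                         scale=cfg.oe_lambda)
            dlogits[is_out] = dreg
            loss += cfg.oe_lambda * reg
        return loss, dlogits

    # softmax head (plain or entropy-regularized exposure)
    loss, d = ce_grad_logits(logits[~is_out], y[~is_out])
    dlogits[~is_out] = d
    if n_out:
        reg, dreg = uniform_ce_grad_logits(logits[is_out], scale=cfg.oe_lambda)
        dlogits[is_out] = dreg
        loss += cfg.oe_lambda * reg
    return loss, dlogits


def train(model: CompactNet, train_set: ImageSet, val_set: ImageSet,
          config: TrainConfig | None = None,
          exposure: ExposureConfig | None = None,
          pool: ImageSet | None = None):
    """Train ``model`` in place; returns ``(model, history)``.

    ``train_set``/``val_set`` must contain every inlier class. When
    ``exposure`` requests outliers (``n_per_class > 0``) they are drawn
    from ``pool`` — never from any test data. The validation loss used
    for scheduling is the cross-entropy of the model's class
    probabilities on the validation inliers, which is comparable across
    heads.
    """
    cfg = config or TrainConfig()
    train_in = train_set.by_role("inlier")
    val_in = val_set.by_role("inlier")
    for c in INLIER_CLASSES[:model.K]:
        if not np.any(train_in.labels == c):
            raise ValueError(f"training set has no samples of inlier class {c!r}")
        if not np.any(val_in.labels == c):
            raise ValueError(f"validation set has no samples of inlier class {c!r}")

    exposed_subset = None
    if exposure is not None and exposure.n_per_class > 0:
        if pool is None or len(pool) == 0:
            raise ValueError("exposure requested but no exposure pool provided")
        exposed_subset = select_exposure_subset(pool, exposure, seed=cfg.seed)

    sampler = ExposureBatchSampler(
        train_in, batch_size=cfg.batch_size, outliers=exposed_subset,
        batch_prob=exposure.batch_prob if exposure is not None else 0.5,
        classes=INLIER_CLASSES[:model.K])

    model.fit_input_norm(train_in.pixels)

    root = np.random.SeedSequence(cfg.seed)
    s_batch, s_aug, s_drop = root.spawn(3)
    rng_batch = np.random.default_rng(s_batch)
    rng_aug = np.random.default_rng(s_aug)
    rng_drop = np.random.default_rng(s_drop)

    class_idx = {c: i for i, c in enumerate(INLIER_CLASSES[:model.K])}
    val_labels = np.array([class_idx[c] for c in val_in.labels])

    lr = cfg.learning_rate
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    best_val = math.inf
    best_params = model.copy_params()
    lr_wait = 0
    stop_wait = 0
    batches_per_epoch = max(1, math.ceil(len(train_in) / cfg.batch_size))
    rows = []

    for epoch in range(cfg.max_epochs):
        annealing = (min(1.0, (epoch + 1) / cfg.kl_anneal_epochs)
                     if cfg.kl_anneal_epochs > 0 else 1.0)
        ep_loss = 0.0
        n_exposed = 0
        n_outlier_imgs = 0
        for _ in range(batches_per_epoch):
            X, y, is_out = sampler.next_batch(rng_batch)
            X = augment_batch(X, cfg.augment, rng_aug)
            cache = model.forward(X, training=True, rng=rng_drop)
            loss, dlogits = _batch_loss_grad(model, cache["logits"], y,
                                             is_out, cfg, annealing)
            grads = model.backward(cache, dlogits)
            for k in model.params:
                velocity[k] = cfg.momentum * velocity[k] - lr * grads[k]
                model.params[k] += velocity[k]
            ep_loss += loss
            if is_out.any():
                n_exposed += 1
                n_outlier_imgs += int(is_out.sum())

        val_loss = loss_ce(model.predict_proba(val_in.pixels), val_labels)
        rows.append({"epoch": epoch, "train_loss": ep_loss / batches_per_epoch,
                     "val_loss": val_loss, "lr": lr,
                     "exposed_batches": n_exposed,
                     "outlier_images": n_outlier_imgs})

        if val_loss < best_val - 1e-4:
            best_val = val_loss
            best_params = model.copy_params()
            lr_wait = 0
            stop_wait = 0
        else:
            lr_wait += 1
            stop_wait += 1
            if lr_wait > cfg.lr_patience and lr > cfg.lr_floor:
                lr = max(lr * cfg.lr_factor, cfg.lr_floor)
                lr_wait = 0
            if stop_wait > cfg.early_stop_patience:
                break

    model.set_params(best_params)
    history = pd.DataFrame(rows)
    history.attrs["exposure_subjects"] = sorted(sampler.outlier_subjects)
    history.attrs["best_val_loss"] = best_val
    return model, history
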