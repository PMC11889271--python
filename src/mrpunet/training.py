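"""Preprocessing, the training recipe, inference, and the ablation harness.

The training recipe: Adam (first-moment
coefficient 0.9), unweighted 2-class cross-entropy, batch size 16, up to 100
epochs, batch-norm running-statistics decay 0.998, and a learning rate that
decays exponentially from 0.01 to 1e-6 across the epoch range (the geometric
law is the one monotone schedule that hits both printed endpoints exactly).
Model selection keeps the epoch with the best validation Dice.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from . import nn
from .metrics import compute_metrics, confusion_counts, evaluate_dataset
from .network import (ABLATION_MODULES, ModelConfig, MRPUNet, ablation_config,
                      build_model)
from .nn import functional as F

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "preprocess", "lr_schedule", "train",
           "predict", "run_ablation", "calibrate_batchnorm"]

_DARK_THRESHOLD = 20.0  # mean 8-bit intensity below which a row/col is "black"


@dataclass
class TrainConfig:
    """The training recipe and its default hyperparameters."""

    batch_size: int = 16
    max_epochs: int = 100
    lr_init: float = 0.01
    lr_final: float = 1e-6
    bn_decay: float = 0.998
    momentum: float = 0.9          # Adam beta1
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    class_weights: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.lr_final <= self.lr_init:
            raise ValueError("need 0 < lr_final <= lr_init")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    epochs: List[int] = field(default_factory=list)
    loss: List[float] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)
    val_dice: List[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "loss": self.loss,
                             "lr": self.lr, "val_dice": self.val_dice})


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _crop_black_border(image: np.ndarray) -> Tuple[slice, slice]:
    """Bounding slices of the non-dark content (device-frame removal)."""
    gray = image.mean(axis=2)
    rows = np.where(gray.mean(axis=1) > _DARK_THRESHOLD)[0]
    cols = np.where(gray.mean(axis=0) > _DARK_THRESHOLD)[0]
    if rows.size == 0 or cols.size == 0:
        raise ValueError("no content after crop: image is entirely dark")
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def preprocess(image: np.ndarray, mask: Optional[np.ndarray] = None,
               target_size: int = 576):
    """Black-border crop + resize to ``target_size``.

    The crop is detected on the image and applied identically to the mask.
    The image is resized bilinearly; the mask with nearest-neighbour and
    re-binarised so it stays strictly {0, 1}.  Returns ``(image, mask)``
    (mask ``None`` if not given); the image comes back as float32 in [0, 1].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {image.shape}")
    rs, cs = _crop_black_border(image)
    cropped = image[rs, cs]
    out = sktransform.resize(cropped.astype(np.float64) / 255.0,
                             (target_size, target_size),
                             order=1, mode="reflect", anti_aliasing=True,
                             preserve_range=True).astype(np.float32)
    out_mask = None
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != image.shape[:2]:
            raise ValueError(f"mask shape {mask.shape} does not match image "
                             f"{image.shape[:2]}")
        mc = mask[rs, cs].astype(np.float32)
        mr = sktransform.resize(mc, (target_size, target_size), order=0,
                                mode="edge", anti_aliasing=False,
                                preserve_range=True)
        out_mask = (mr > 0.5).astype(np.uint8)
    return out, out_mask


def _to_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    """Stack HxWx3 float images into a [B, 3, H, W] float32 batch."""
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Exponential decay hitting lr_init at epoch 0 and lr_final at the last.

    lr(e) = lr_init * (lr_final / lr_init) ** (e / (max_epochs - 1)).
    """
    if not 0 <= epoch < cfg.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.max_epochs})")
    if cfg.max_epochs == 1:
        return cfg.lr_init
    frac = epoch / (cfg.max_epochs - 1)
    return float(cfg.lr_init * (cfg.lr_final / cfg.lr_init) ** frac)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def predict(model: MRPUNet, images: Sequence[np.ndarray],
            batch_size: int = 8) -> List[np.ndarray]:
    """Binary masks by class-argmax of the 2-channel scores.

    Ties break toward the background class (argmax returns the first
    maximum), so an all-zero head predicts background everywhere.  Inputs
    must already be preprocessed to the model's input size (HxWx3 floats).
    """
    model.eval()
    masks: List[np.ndarray] = []
    for start in range(0, len(images), batch_size):
        batch = _to_batch(images[start:start + batch_size])
        scores = model.predict_scores(batch)
        masks.extend(np.argmax(scores, axis=1).astype(np.uint8))
    return masks


def calibrate_batchnorm(model: MRPUNet, images: Sequence[np.ndarray],
                        batch_size: int = 16) -> None:
    """Recompute BN running statistics as exact averages over ``images``.

    With the slow 0.998 running-statistics decay and short runs, the stored
    estimates lag far behind the real activation statistics, so eval-mode
    outputs would not reflect the trained network.  This pass (precise BN)
    replaces them with the cumulative average of per-batch statistics over
    the training set; dropout is kept inactive so the statistics are those
    of the deterministic forward pass.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    if not bns:
        return
    model.train()
    for m in model.modules():
        if isinstance(m, nn.Dropout2d):
            object.__setattr__(m, "training", False)
    saved_decay = [bn.decay for bn in bns]
    try:
        step = 0
        for start in range(0, len(images), batch_size):
            batch = _to_batch(images[start:start + batch_size])
            for bn in bns:  # cumulative moving average of batch statistics
                bn.decay = step / (step + 1)
            model(batch)
            step += 1
    finally:
        for bn, d in zip(bns, saved_decay):
            bn.decay = d
        model.eval()


def _mean_dice(model: MRPUNet, images, masks, batch_size: int) -> float:
    preds = predict(model, images, batch_size=batch_size)
    return float(np.mean([
        compute_metrics(confusion_counts(p, t))["dc"]
        for p, t in zip(preds, masks)]))


def train(model: MRPUNet, train_set: Tuple[Sequence, Sequence],
          val_set: Tuple[Sequence, Sequence], cfg: TrainConfig,
          log_every: int = 1) -> Tuple[MRPUNet, TrainHistory]:
    """Fit ``model`` and return it loaded with the best-validation-Dice weights.

    ``train_set``/``val_set`` are ``(images, masks)`` with images already
    preprocessed to the model input size (HxWx3 float32 in [0, 1]) and masks
    binary HxW.  Shuffling, dropout and everything else stochastic derive
    from ``cfg.seed``.  Aborts with a diagnostic if the loss goes non-finite.
    """
    images, masks = list(train_set[0]), list(train_set[1])
    val_images, val_masks = list(val_set[0]), list(val_set[1])
    if not images or not val_images:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    for lvl, enc in enumerate(model.encoders):
        if hasattr(enc, "drop"):
            enc.drop.reseed(cfg.seed + 977 * (lvl + 1))

    opt = nn.Adam(model.parameters(), lr=cfg.lr_init, beta1=cfg.momentum)
    weights = (np.asarray(cfg.class_weights, dtype=np.float32)
               if cfg.class_weights is not None else None)

    history = TrainHistory()
    best_dice, best_state = -1.0, None
    n = len(images)
    for epoch in range(cfg.max_epochs):
        lr = lr_schedule(epoch, cfg)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        epoch_loss, t0 = 0.0, time.time()
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = _to_batch([images[i] for i in idx])
            yb = np.stack([masks[i] for i in idx]).astype(np.int64)
            logits = model(xb)
            loss = F.softmax_cross_entropy(logits, yb, class_weights=weights)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}, "
                    f"lr {lr:.3g}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss_val * len(idx)
        epoch_loss /= n

        calibrate_batchnorm(model, images, cfg.batch_size)
        val_dice = _mean_dice(model, val_images, val_masks, cfg.batch_size)
        history.epochs.append(epoch)
        history.loss.append(epoch_loss)
        history.lr.append(lr)
        history.val_dice.append(val_dice)
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = model.state_dict()
            history.best_epoch = epoch
        if log_every and epoch % log_every == 0:
            print(f"epoch {epoch:3d}  loss {epoch_loss:.4f}  lr {lr:.3g}  "
                  f"val_dice {val_dice:.4f}  ({time.time() - t0:.1f}s)",
                  file=sys.stderr)

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def run_ablation(data: Tuple[Sequence, Sequence, Sequence, Sequence],
                 base_model_cfg: ModelConfig, train_cfg: TrainConfig,
                 modules: Optional[Sequence[str]] = None,
                 seed: int = 0) -> pd.DataFrame:
    """Train and evaluate each architecture configuration on one dataset.

    ``data`` is ``(train_images, train_masks, test_images, test_masks)``.
    Each row reports the five metrics (per-image mean) for one configuration;
    a failed run is recorded in its row's ``error`` column and the sweep
    continues.  Seeds are fixed per row so reruns reproduce the table.
    """
    tr_im, tr_ma, te_im, te_ma = data
    names = list(modules) if modules is not None else list(ABLATION_MODULES)
    rows = []
    for name in names:
        row: Dict[str, object] = {"module": name}
        try:
            cfg = ablation_config(name, base=base_model_cfg)
            model = build_model(cfg, seed=seed)
            tcfg = dataclasses.replace(train_cfg, seed=seed)
            model, _ = train(model, (tr_im, tr_ma), (te_im, te_ma), tcfg)
            preds = predict(model, te_im, batch_size=tcfg.batch_size)
            report = evaluate_dataset(preds, te_ma, aggregation="per_image_mean")
            row.update(report.as_dict())
            row["error"] = ""
        except Exception as exc:  # keep sweeping; record the failure
            logger.exception("ablation run %s failed", name)
            row.update({k: np.nan for k in ("acc", "sen", "spe", "ji", "dc")})
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
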