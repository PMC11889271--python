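"""scikit-learn style facade over the segmentation network.

:class:`MRPUNetSegmenter` wraps model construction, preprocessing, the
training loop and argmax inference behind the familiar ``fit`` / ``predict``
estimator contract, so the segmenter composes with sklearn model selection
and pipelines.  All architecture switches are constructor parameters, which
makes the ablation lattice reachable through ``set_params`` /
``GridSearchCV`` as well.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import evaluate_dataset
from .network import ModelConfig, build_model
from .training import TrainConfig, predict as _predict, preprocess, train as _train

__all__ = ["MRPUNetSegmenter"]


class MRPUNetSegmenter(BaseEstimator):
    """Dermoscopic lesion segmenter with a fit/predict interface.

    Parameters mirror :class:`~mrpunet.network.ModelConfig` and
    :class:`~mrpunet.training.TrainConfig`.  ``X`` is a sequence of HxWx3
    uint8 (or [0,1] float) RGB images of any size — each is black-border
    cropped and resized to ``input_size`` internally; ``y`` is the aligned
    sequence of binary masks.

    Attributes (after ``fit``)
    --------------------------
    model_ : MRPUNet
        The trained network (best validation-Dice weights).
    history_ : TrainHistory
        Per-epoch loss, learning rate and validation Dice.
    n_parameters_ : int
        Trainable parameter count.
    """

    def __init__(self, input_size: int = 96,
                 level_channels: Tuple[int, ...] = (8, 16, 32, 64),
                 bottleneck_channels: int = 128, n_groups: int = 4,
                 se_reduction: int = 16, dropout_rate: float = 0.2,
                 dilation_rates: Tuple[int, ...] = (1, 2, 4, 8),
                 use_mif: bool = True, use_res2net: bool = True,
                 use_se: bool = True, use_pdc: bool = True,
                 batch_size: int = 16, max_epochs: int = 25,
                 lr_init: float = 0.01, lr_final: float = 1e-6,
                 bn_decay: float = 0.998, momentum: float = 0.9,
                 validation_fraction: float = 0.2, random_state: int = 0):
        self.input_size = input_size
        self.level_channels = level_channels
        self.bottleneck_channels = bottleneck_channels
        self.n_groups = n_groups
        self.se_reduction = se_reduction
        self.dropout_rate = dropout_rate
        self.dilation_rates = dilation_rates
        self.use_mif = use_mif
        self.use_res2net = use_res2net
        self.use_se = use_se
        self.use_pdc = use_pdc
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.lr_init = lr_init
        self.lr_final = lr_final
        self.bn_decay = bn_decay
        self.momentum = momentum
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- config assembly ------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            input_size=self.input_size,
            level_channels=list(self.level_channels),
            bottleneck_channels=self.bottleneck_channels,
            n_groups=self.n_groups, se_reduction=self.se_reduction,
            dropout_rate=self.dropout_rate,
            dilation_rates=tuple(self.dilation_rates),
            bn_decay=self.bn_decay, use_mif=self.use_mif,
            use_res2net=self.use_res2net, use_se=self.use_se,
            use_pdc=self.use_pdc)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(batch_size=self.batch_size, max_epochs=self.max_epochs,
                           lr_init=self.lr_init, lr_final=self.lr_final,
                           bn_decay=self.bn_decay, momentum=self.momentum,
                           seed=self.random_state)

    def _prepare(self, X, y=None):
        images, masks = [], []
        for i, img in enumerate(X):
            img = np.asarray(img)
            if img.dtype != np.uint8:
                img = (np.clip(img, 0, 1) * 255).astype(np.uint8)
            m = np.asarray(y[i]) if y is not None else None
            im, mm = preprocess(img, m, target_size=self.input_size)
            images.append(im)
            if y is not None:
                masks.append(mm)
        return images, masks

    # -- sklearn API -----------------------------------------------------------

    def fit(self, X: Sequence[np.ndarray], y: Sequence[np.ndarray],
            X_val: Optional[Sequence[np.ndarray]] = None,
            y_val: Optional[Sequence[np.ndarray]] = None) -> "MRPUNetSegmenter":
        """Train on image/mask pairs.

        If no explicit validation set is given, a ``validation_fraction``
        tail split (seeded by ``random_state``) is held out for model
        selection.
        """
        if len(X) != len(y):
            raise ValueError(f"{len(X)} images vs {len(y)} masks")
        images, masks = self._prepare(X, y)
        if X_val is not None:
            val_images, val_masks = self._prepare(X_val, y_val)
        else:
            rng = np.random.default_rng(self.random_state)
            n_val = max(1, int(round(len(images) * self.validation_fraction)))
            order = rng.permutation(len(images))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            if tr_idx.size == 0:
                raise ValueError("not enough samples to hold out validation data")
            val_images = [images[i] for i in val_idx]
            val_masks = [masks[i] for i in val_idx]
            images = [images[i] for i in tr_idx]
            masks = [masks[i] for i in tr_idx]

        model = build_model(self._model_config(), seed=self.random_state)
        model, history = _train(model, (images, masks), (val_images, val_masks),
                                self._train_config())
        self.model_ = model
        self.history_ = history
        self.n_parameters_ = int(sum(p.data.size for p in model.parameters()))
        return self

    def predict(self, X: Sequence[np.ndarray]) -> List[np.ndarray]:
        """Binary lesion masks at ``input_size`` resolution, one per image."""
        self._check_fitted()
        images, _ = self._prepare(X)
        return _predict(self.model_, images, batch_size=self.batch_size)

    def score(self, X: Sequence[np.ndarray], y: Sequence[np.ndarray]) -> float:
        """Mean per-image Dice coefficient against the given masks."""
        self._check_fitted()
        images, masks = self._prepare(X, y)
        preds = _predict(self.model_, images, batch_size=self.batch_size)
        return evaluate_dataset(preds, masks, aggregation="per_image_mean").dc

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this MRPUNetSegmenter instance is not fitted yet")
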