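"""scikit-learn style estimator facade over the training/inference stack.

``LesionSegmenter`` is a conventional ``fit``/``predict`` estimator
(``get_params``/``set_params``, clonable, fitted attributes with a
trailing underscore) so the segmentation model composes with sklearn
tooling; it wraps the same trainer and sliding-window predictor the
pipeline uses.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .augmentation import AugmentConfig
from .evaluation import dice
from .inference import InferenceConfig, predict_volume
from .network import NetworkConfig
from .preprocessing import PreprocessPlan, compute_target_spacing, preprocess_volume, resample
from .training import TrainConfig, Trainer, _Case
from .volume_io import LabelMap, Volume


class LesionSegmenter(BaseEstimator):
    """Multi-class 3-D lesion segmenter (residual U-Net, sliding-window TTA).

    Parameters mirror the network/training/inference configs; ``fit``
    takes sequences of :class:`~ovaseg.volume_io.Volume` and
    :class:`~ovaseg.volume_io.LabelMap`.

    Attributes (after ``fit``)
    --------------------------
    network_ : the trained network
    plan_ : the preprocessing plan (median cohort spacing unless given)
    history_ : per-step training log (step, lr, loss)
    classes_ : the label values the model predicts
    """

    def __init__(self, variant="resnet_unet", base_filters=8,
                 blocks_per_stage=(1, 2, 6, 3), deep_supervision=True,
                 patch_size=(16, 16, 16), batch_size=2, total_steps=600,
                 peak_lr=0.02, momentum=0.98, weight_decay=1e-4,
                 schedule="warmup_cosine", p_foreground=1.0 / 3.0,
                 target_spacing=None, augment=None, tta=True,
                 window_step_fraction=0.5, random_state=0):
        self.variant = variant
        self.base_filters = base_filters
        self.blocks_per_stage = blocks_per_stage
        self.deep_supervision = deep_supervision
        self.patch_size = patch_size
        self.batch_size = batch_size
        self.total_steps = total_steps
        self.peak_lr = peak_lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.schedule = schedule
        self.p_foreground = p_foreground
        self.target_spacing = target_spacing
        self.augment = augment
        self.tta = tta
        self.window_step_fraction = window_step_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _configs(self, spacing):
        net_cfg = NetworkConfig(variant=self.variant, base_filters=self.base_filters,
                                n_stages=len(self.blocks_per_stage),
                                blocks_per_stage=tuple(self.blocks_per_stage),
                                deep_supervision=self.deep_supervision,
                                spacing=tuple(spacing))
        train_cfg = TrainConfig(batch_size=self.batch_size, total_steps=self.total_steps,
                                peak_lr=self.peak_lr, momentum=self.momentum,
                                weight_decay=self.weight_decay, schedule=self.schedule,
                                patch_size=tuple(self.patch_size),
                                p_foreground=self.p_foreground, seed=self.random_state)
        inf_cfg = InferenceConfig(window_size=tuple(self.patch_size), tta=self.tta,
                                  step_fraction=self.window_step_fraction)
        return net_cfg, train_cfg, inf_cfg

    def fit(self, X: Sequence[Volume], y: Sequence[LabelMap]) -> "LesionSegmenter":
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be equal-length, non-empty sequences")
        spacing = (tuple(self.target_spacing) if self.target_spacing is not None
                   else compute_target_spacing([v.spacing for v in X]))
        self.plan_ = PreprocessPlan(target_spacing=spacing)
        cases = []
        for vol, lab in zip(X, y):
            if vol.shape != lab.shape:
                raise ValueError(f"volume/labels misaligned for {vol.scan_id}")
            pv = preprocess_volume(vol, self.plan_)
            pl = resample(lab, spacing)
            cases.append(_Case(vol.scan_id, pv.values.astype(np.float32),
                               pl.labels.astype(np.int64)))
        net_cfg, train_cfg, _ = self._configs(spacing)
        aug = self.augment if self.augment is not None else AugmentConfig()
        trainer = Trainer(cases, net_cfg, train_cfg, aug,
                          init_seed=self.random_state,
                          sample_seed=self.random_state + 1000)
        self.network_ = trainer.run()
        self.history_ = trainer.history
        self.classes_ = np.arange(net_cfg.n_classes)
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise AttributeError("this LesionSegmenter is not fitted yet; call fit first")

    def predict(self, X: Sequence[Volume]) -> list[LabelMap]:
        """Native-grid label maps for each volume."""
        self._check_fitted()
        _, _, inf_cfg = self._configs(self.plan_.target_spacing)
        out = []
        for vol in X:
            _, labels = predict_volume(vol, [self.network_], inf_cfg, self.plan_)
            out.append(labels)
        return out

    def predict_proba(self, X: Sequence[Volume]):
        """Per-class probability grids (on the preprocessed grid)."""
        self._check_fitted()
        _, _, inf_cfg = self._configs(self.plan_.target_spacing)
        return [predict_volume(vol, [self.network_], inf_cfg, self.plan_)[0] for vol in X]

    def score(self, X: Sequence[Volume], y: Sequence[LabelMap]) -> float:
        """Mean foreground Dice (0-1) over the given scans."""
        preds = self.predict(X)
        vals = []
        for p, g in zip(preds, y):
            d = dice((p.labels > 0).astype(np.uint8), (g.labels > 0).astype(np.uint8), 1)
            if np.isfinite(d):
                vals.append(d / 100.0)
        return float(np.mean(vals)) if vals else float("nan")
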