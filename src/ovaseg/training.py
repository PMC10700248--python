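"""Optimisation recipe, patch sampling, loss, grouped CV and full-data training.

The tuned recipe is SGD with Nesterov momentum 0.98, weight decay 1e-4,
batch size 4 and a linear-warmup + cosine-decay schedule peaking at 0.02;
the baseline recipe is momentum 0.99, weight decay 3e-5, batch size 2 and
a polynomial decay from 0.01 to 0 over 250,000 steps.  The loss is the
sum of soft-Dice and cross-entropy, with deep supervision as a weighted
sum over decoder scales.  Cross-validation folds are assigned per
patient so that no patient's scans span folds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import volume_io
from .augmentation import AugmentConfig, augment_pair
from ._nn import SGDNesterov
from .network import NetworkConfig, SegNetwork, build_network, softmax_probabilities
from .preprocessing import PreprocessPlan, preprocess_volume, resample

__all__ = ["TrainConfig", "lr_at_step", "combined_loss", "sample_patch",
           "assign_folds", "train", "Trainer", "save_checkpoint", "load_checkpoint"]

# additive smoothing of the soft-Dice ratio; order-1 so that a class absent
# from a batch yields Dice ~ 1 with a bounded gradient instead of a huge
# suppressive one when the predicted class mass is also near zero
DICE_EPS = 1.0


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    batch_size: int = 4
    total_steps: int = 250_000
    momentum: float = 0.98
    weight_decay: float = 1e-4
    schedule: Literal["warmup_cosine", "poly"] = "warmup_cosine"
    peak_lr: float = 0.02
    warmup_fraction: float = 0.02
    poly_exponent: float = 0.9
    patch_size: tuple[int, int, int] = (16, 16, 16)
    p_foreground: float = 1.0 / 3.0
    #: draw the oversampled foreground voxel from a uniformly chosen present
    #: class, so sparse classes are anchored as often as bulky ones
    class_balanced_sampling: bool = True
    k_folds: int = 5
    n_full_models: int = 3
    log_every: int = 250
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self):
        if not 0 < self.momentum < 1:
            raise ValueError("momentum must be in (0, 1)")
        if self.peak_lr <= 0:
            raise ValueError("peak learning rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if not 0 <= self.warmup_fraction < 1:
            raise ValueError("warmup fraction must be in [0, 1)")
        if not 0 <= self.p_foreground <= 1:
            raise ValueError("p_foreground must be in [0, 1]")
        return self

    @classmethod
    def baseline(cls, **over) -> "TrainConfig":
        """The suggested baseline recipe."""
        kw = dict(batch_size=2, momentum=0.99, weight_decay=3e-5,
                  schedule="poly", peak_lr=0.01)
        kw.update(over)
        return cls(**kw)


def lr_at_step(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Learning rate at ``step`` (0 .. total_steps inclusive)."""
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} out of range [0, {total_steps}]")
    if cfg.schedule == "poly":
        return cfg.peak_lr * (1.0 - step / total_steps) ** cfg.poly_exponent
    warmup = int(round(cfg.warmup_fraction * total_steps))
    if step <= warmup and warmup > 0:
        return cfg.peak_lr * step / warmup
    t = (step - warmup) / max(total_steps - warmup, 1)
    return cfg.peak_lr * 0.5 * (1.0 + np.cos(np.pi * t))


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[target]


def _loss_single(scores: np.ndarray, target: np.ndarray):
    """Soft-Dice + cross-entropy on one scale; returns (loss, dL/dscores).

    Dice is pooled over the batch ("batch Dice") per foreground class —
    this keeps classes absent from individual patches from being punished
    for any probability mass, which would otherwise suppress the sparse
    omental class — then averaged; cross-entropy is the mean over voxels.
    """
    n, d, h, w, c = scores.shape
    if target.shape != (n, d, h, w):
        raise ValueError(f"scores {scores.shape[:4]} and target {target.shape} misaligned")
    p = softmax_probabilities(scores)
    onehot = _one_hot(target, c)
    nvox = n * d * h * w

    # cross-entropy
    pt = np.clip(np.take_along_axis(p, target[..., None], axis=-1), 1e-12, None)
    ce = float(-np.log(pt).mean())
    dce_dp = (-onehot / np.clip(p, 1e-12, None)) / nvox

    # batch-pooled soft Dice over foreground classes
    axes = (0, 1, 2, 3)
    inter = (p * onehot).sum(axis=axes)  # (c,)
    psum = p.sum(axis=axes)
    gsum = onehot.sum(axis=axes)
    num = 2.0 * inter + DICE_EPS
    den = psum + gsum + DICE_EPS
    dice = num / den  # (c,)
    fg = slice(1, None)
    dice_term = float(1.0 - dice[fg].mean())
    # d(dice_c)/dp_c = (2*g*den - num)/den^2, pooled sums
    m = c - 1
    ddice_dp = np.zeros_like(p)
    ddice_dp[..., fg] = ((2.0 / den)[fg] * onehot[..., fg] - (num / den ** 2)[fg]) / m
    dl_dp = dce_dp - ddice_dp

    # chain through softmax: dL/dz = p * (dl_dp - sum_c dl_dp * p)
    dot = (dl_dp * p).sum(axis=-1, keepdims=True)
    dl_dz = p * (dl_dp - dot)
    return ce + dice_term, dl_dz.astype(scores.dtype)


def _downsample_target(target: np.ndarray, factor: tuple[int, int, int]) -> np.ndarray:
    return target[:, ::factor[0], ::factor[1], ::factor[2]]


def combined_loss(scores, target, return_grad: bool = False):
    """Soft-Dice + cross-entropy loss.

    ``scores`` may be a single ``(N, D, H, W, C)`` array or a
    ``{level: scores}`` dict from a deep-supervision forward pass, in
    which case the per-level losses are weighted by 0.5**level
    (normalised) and targets are nearest-neighbour downsampled.
    """
    if isinstance(scores, dict):
        levels = sorted(scores)
        weights = np.array([0.5 ** lv for lv in levels])
        weights /= weights.sum()
        total, grads = 0.0, {}
        for lv, wgt in zip(levels, weights):
            s = scores[lv]
            fac = tuple(int(round(t / o)) for t, o in zip(target.shape[1:], s.shape[1:4]))
            tgt = _downsample_target(target, fac)
            val, g = _loss_single(s, tgt)
            total += wgt * val
            grads[lv] = wgt * g
        return (total, grads) if return_grad else total
    val, g = _loss_single(np.asarray(scores), np.asarray(target))
    return (val, g) if return_grad else val


def sample_patch(volume: np.ndarray, labels: np.ndarray, patch_size,
                 p_fg: float, rng: np.random.Generator, jitter: bool = True,
                 per_class: bool = False):
    """Sample an aligned (image, label) patch pair.

    With probability ``p_fg`` the patch is anchored on a uniformly chosen
    foreground voxel (when any exist): by default the patch position is
    uniform among positions containing that voxel, which avoids training
    the network on exclusively lesion-centred statistics; with
    ``jitter=False`` the patch is centred on it.  With ``per_class=True``
    the anchor voxel is drawn from a uniformly chosen *present* foreground
    class, so sparse classes are sampled as often as bulky ones.
    Otherwise the position is uniform over all valid positions.  Volumes
    smaller than the patch are symmetrically zero-padded (labels padded
    with background).
    """
    patch_size = tuple(int(p) for p in patch_size)
    pads = [max(0, p - s) for p, s in zip(patch_size, volume.shape)]
    if any(pads):
        pad = [((p + 1) // 2, p // 2) for p in pads]
        volume = np.pad(volume, pad)
        labels = np.pad(labels, pad)
    max_start = [s - p for s, p in zip(volume.shape, patch_size)]
    fg = None
    if rng.uniform() < p_fg:
        if per_class:
            present = [c for c in np.unique(labels) if c > 0]
            if present:
                cls = present[rng.integers(len(present))]
                fg_idx = np.argwhere(labels == cls)
                fg = fg_idx[rng.integers(len(fg_idx))]
        else:
            fg_idx = np.argwhere(labels > 0)
            if len(fg_idx):
                fg = fg_idx[rng.integers(len(fg_idx))]
    if fg is not None and jitter:
        start = [int(rng.integers(max(0, f - p + 1), min(m, f) + 1))
                 for f, p, m in zip(fg, patch_size, max_start)]
    elif fg is not None:
        start = [int(np.clip(f - p // 2, 0, m)) for f, p, m in zip(fg, patch_size, max_start)]
    else:
        start = [int(rng.integers(0, m + 1)) for m in max_start]
    sl = tuple(slice(s, s + p) for s, p in zip(start, patch_size))
    return volume[sl], labels[sl]


def assign_folds(manifest: pd.DataFrame, k: int, seed: int) -> dict[str, int]:
    """Patient-grouped fold assignment: scan_id -> fold index.

    All scans of one patient share a fold, and per-fold patient counts
    differ by at most one.  Deterministic in ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    patients = sorted(manifest["patient_id"].unique())
    if len(patients) < k:
        raise ValueError(f"{len(patients)} patients cannot fill {k} folds")
    order = np.random.default_rng(seed).permutation(len(patients))
    fold_of_patient = {patients[j]: i % k for i, j in enumerate(order)}
    return {row.scan_id: fold_of_patient[row.patient_id]
            for row in manifest.itertuples()}


# --------------------------------------------------------------------------
# checkpoints

def save_checkpoint(net: SegNetwork, path, meta: Optional[dict] = None) -> Path:
    path = Path(path)
    meta = dict(meta or {})
    meta["network_config"] = net.config.model_dump()
    np.savez_compressed(path, __meta__=np.frombuffer(
        yaml.safe_dump(meta).encode(), dtype=np.uint8), **net.state_dict())
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path) -> tuple[SegNetwork, dict]:
    with np.load(Path(path)) as data:
        meta = yaml.safe_load(bytes(data["__meta__"]).decode())
        cfg = NetworkConfig(**meta.pop("network_config"))
        net = build_network(cfg, seed=0)
        net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return net, meta


# --------------------------------------------------------------------------
# trainer

@dataclasses.dataclass
class _Case:
    scan_id: str
    image: np.ndarray
    labels: np.ndarray


def _load_cases(manifest: pd.DataFrame, plan: PreprocessPlan) -> list[_Case]:
    cases = []
    for row in manifest.itertuples():
        vol = volume_io.read_volume(row.image)
        lab = volume_io.read_labelmap(row.label)
        vol = preprocess_volume(vol, plan)
        lab = resample(lab, plan.target_spacing)
        cases.append(_Case(row.scan_id, vol.values.astype(np.float32),
                           lab.labels.astype(np.int64)))
    return cases


class Trainer:
    """Single-model training loop over preprocessed in-memory cases."""

    def __init__(self, cases: list[_Case], net_cfg: NetworkConfig, cfg: TrainConfig,
                 aug_cfg: Optional[AugmentConfig] = None, init_seed: int = 0,
                 sample_seed: int = 0, log_path: Optional[Path] = None):
        self.cases = cases
        self.cfg = cfg
        self.aug_cfg = aug_cfg if aug_cfg is not None else AugmentConfig()
        self.net = build_network(net_cfg, seed=init_seed)
        self.opt = SGDNesterov(self.net.parameters(), cfg.momentum, cfg.weight_decay)
        self.rng = np.random.default_rng(sample_seed)
        self.log_path = Path(log_path) if log_path else None
        self.history: list[dict] = []

    def _batch(self):
        imgs, labs = [], []
        for _ in range(self.cfg.batch_size):
            case = self.cases[self.rng.integers(len(self.cases))]
            img, lab = sample_patch(case.image, case.labels, self.cfg.patch_size,
                                    self.cfg.p_foreground, self.rng,
                                    per_class=self.cfg.class_balanced_sampling)
            img, lab = augment_pair(img, lab, self.aug_cfg, self.rng)
            imgs.append(img)
            labs.append(lab)
        return (np.stack(imgs)[..., None].astype(np.float32),
                np.stack(labs).astype(np.int64))

    def run(self) -> SegNetwork:
        cfg = self.cfg
        log_f = self.log_path.open("w") if self.log_path else None
        try:
            for step in range(1, cfg.total_steps + 1):
                x, y = self._batch()
                outs = self.net.forward(x, train=True)
                loss, grads = combined_loss(outs, y, return_grad=True)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at step {step}")
                self.opt.zero_grad()
                self.net.backward(grads)
                lr = lr_at_step(step, cfg.total_steps, cfg)
                self.opt.step(lr)
                rec = {"step": step, "lr": float(lr), "loss": float(loss)}
                self.history.append(rec)
                if log_f and (step % cfg.log_every == 0 or step in (1, cfg.total_steps)):
                    log_f.write(json.dumps(rec) + "\n")
        finally:
            if log_f:
                log_f.close()
        return self.net


def train(manifest: pd.DataFrame, net_cfg: NetworkConfig, cfg: TrainConfig,
          mode: Literal["cv", "full"] = "full", *, plan: Optional[PreprocessPlan] = None,
          aug_cfg: Optional[AugmentConfig] = None, out_dir="./models",
          inference_cfg=None) -> dict:
    """Train in cross-validation or full-data multi-seed mode.

    ``cv``: one checkpoint per fold plus an out-of-fold prediction of every
    scan by the model that never saw that patient.  ``full``:
    ``cfg.n_full_models`` checkpoints from distinct initialisation seeds,
    to be ensembled at inference.  Returns paths of checkpoints (and
    out-of-fold predictions in cv mode).
    """
    from .inference import InferenceConfig, predict_volume  # cycle-free at runtime

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = plan or PreprocessPlan()
    ss = np.random.SeedSequence(cfg.seed)
    fold_seed, base_seed = [int(s) for s in ss.generate_state(2) % (2 ** 31)]
    cases = _load_cases(manifest, plan)
    by_id = {c.scan_id: c for c in cases}
    result = {"checkpoints": [], "oof_predictions": {}, "folds": None}

    if mode == "cv":
        folds = assign_folds(manifest, cfg.k_folds, fold_seed)
        result["folds"] = folds
        inference_cfg = inference_cfg or InferenceConfig(window_size=cfg.patch_size)
        for fold in range(cfg.k_folds):
            train_ids = [sid for sid, f in folds.items() if f != fold]
            val_rows = manifest[manifest["scan_id"].map(folds) == fold]
            if not train_ids:
                raise ValueError(f"fold {fold} leaves no training scans")
            trainer = Trainer([by_id[s] for s in train_ids], net_cfg, cfg, aug_cfg,
                              init_seed=base_seed + fold, sample_seed=base_seed + 1000 + fold,
                              log_path=out_dir / f"train_fold{fold}.jsonl")
            net = trainer.run()
            ckpt = save_checkpoint(net, out_dir / f"fold{fold}.npz",
                                   {"mode": "cv", "fold": fold,
                                    "train_scans": train_ids})
            result["checkpoints"].append(ckpt)
            pred_dir = out_dir / "oof_predictions"
            pred_dir.mkdir(exist_ok=True)
            for row in val_rows.itertuples():
                vol = volume_io.read_volume(row.image)
                _, labmap = predict_volume(vol, [net], inference_cfg, plan)
                labmap.scan_id = row.scan_id
                p = volume_io.write_labelmap(labmap, pred_dir / f"{row.scan_id}.nii.gz")
                result["oof_predictions"][row.scan_id] = p
    elif mode == "full":
        for m in range(cfg.n_full_models):
            trainer = Trainer(cases, net_cfg, cfg, aug_cfg,
                              init_seed=base_seed + m, sample_seed=base_seed + 1000 + m,
                              log_path=out_dir / f"train_model{m}.jsonl")
            net = trainer.run()
            result["checkpoints"].append(
                save_checkpoint(net, out_dir / f"model{m}.npz",
                                {"mode": "full", "member": m}))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return result
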