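"""Gaussian-weighted sliding-window inference with eight-flip TTA.

Each window is evaluated under all 8 combinations of axis flips; scores
are inverse-flipped, converted to probabilities, weighted by a separable
Gaussian centred mid-window and accumulated.  The accumulated grid is
normalised by the accumulated weights (strictly positive everywhere by
coverage), ensemble members are averaged voxelwise, and the argmax label
map (ties towards the lower class index) is restored to the native grid.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .network import softmax_probabilities
from .preprocessing import PreprocessPlan, preprocess_volume, restore_to_original
from .volume_io import LabelMap, Volume

__all__ = ["InferenceConfig", "ProbabilityGrid", "window_positions",
           "gaussian_window", "tta_transforms", "predict_volume", "sliding_window_predict"]


class InferenceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    window_size: tuple[int, int, int] = (16, 16, 16)
    step_fraction: float = 0.5
    sigma_scale: float = 0.125  # Gaussian sd as a fraction of the window size
    tta: bool = True

    @model_validator(mode="after")
    def _valid(self):
        if not 0 < self.step_fraction <= 1:
            raise ValueError("step fraction must be in (0, 1]")
        if self.sigma_scale <= 0:
            raise ValueError("sigma scale must be > 0")
        return self


@dataclasses.dataclass
class ProbabilityGrid:
    """Per-class soft prediction over a volume grid (classes last)."""

    probabilities: np.ndarray  # (D, H, W, C)
    spacing: tuple[float, float, float]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        s = self.probabilities.sum(axis=-1)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("per-voxel probabilities must sum to 1")


def window_positions(shape, window, step_fraction: float) -> list[tuple[int, ...]]:
    """Lexicographically sorted window start coordinates.

    Windows are evenly spaced with a target step of
    ``step_fraction * window``; the last window per axis is flush with
    the volume end, and every voxel is covered by at least one window.
    """
    per_axis = []
    for length, w in zip(shape, window):
        if w > length:
            raise ValueError(f"window {w} exceeds axis length {length} (pad first)")
        if length == w:
            per_axis.append([0])
            continue
        target = max(w * step_fraction, 1e-9)
        n = int(np.ceil((length - w) / target)) + 1
        actual = (length - w) / (n - 1)
        per_axis.append([int(round(i * actual)) for i in range(n)])
    return sorted(itertools.product(*per_axis))


def gaussian_window(window, sigma_scale: float) -> np.ndarray:
    """Separable Gaussian weight grid, centred mid-window, max 1."""
    axes = []
    for w in window:
        centre = (w - 1) / 2.0
        sigma = sigma_scale * w
        d = np.arange(w) - centre
        axes.append(np.exp(-(d ** 2) / (2.0 * sigma ** 2)))
    out = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    out /= out.max()  # even-sized windows have no voxel exactly at the centre
    assert (out > 0).all()
    return out


def tta_transforms() -> list[tuple]:
    """All 8 axis-flip transforms as (forward, inverse) callable pairs.

    The first entry is the identity; flips are involutions, so forward
    and inverse coincide.  Callables act on the 3 leading (spatial) axes.
    """
    out = []
    for axes in itertools.chain.from_iterable(
            itertools.combinations(range(3), r) for r in range(4)):
        def f(x, axes=axes):
            return np.flip(x, axis=axes) if axes else x
        out.append((f, f))
    return out


def _pad_to_window(arr, window):
    pads = [max(0, w - s) for w, s in zip(window, arr.shape)]
    pad = [((p + 1) // 2, p // 2) for p in pads]
    return np.pad(arr, pad), pad


def sliding_window_predict(image: np.ndarray, networks: Sequence, cfg: InferenceConfig,
                           n_classes: Optional[int] = None) -> np.ndarray:
    """Ensemble-mean per-class probability grid for a preprocessed image.

    ``networks`` are callables mapping ``(N, D, H, W, 1)`` patches to
    ``(N, D, H, W, C)`` scores (e.g. :class:`~ovaseg.network.SegNetwork`).
    """
    n_classes = n_classes or getattr(networks[0], "n_classes", None)
    if n_classes is None:
        raise ValueError("n_classes not given and not exposed by the network")
    window = tuple(cfg.window_size)
    padded, pad = _pad_to_window(np.asarray(image, dtype=np.float32), window)
    positions = window_positions(padded.shape, window, cfg.step_fraction)
    weights = gaussian_window(window, cfg.sigma_scale).astype(np.float32)
    transforms = tta_transforms() if cfg.tta else tta_transforms()[:1]

    member_probs = []
    for net in networks:
        acc = np.zeros((*padded.shape, n_classes), dtype=np.float32)
        wacc = np.zeros(padded.shape, dtype=np.float32)
        for pos in positions:
            sl = tuple(slice(p, p + w) for p, w in zip(pos, window))
            patch = padded[sl]
            batch = np.stack([fwd(patch) for fwd, _ in transforms])[..., None]
            scores = np.asarray(net(batch))
            probs = softmax_probabilities(scores)
            mean_p = np.mean([inv(probs[i]) for i, (_, inv) in enumerate(transforms)],
                             axis=0)
            acc[sl] += weights[..., None] * mean_p
            wacc[sl] += weights
        assert (wacc > 0).all(), "uncovered voxel: sliding-window coverage violated"
        member_probs.append(acc / wacc[..., None])
    prob = np.mean(member_probs, axis=0)
    # undo padding
    sl = tuple(slice(p[0], p[0] + s) for p, s in zip(pad, image.shape))
    prob = prob[sl]
    prob /= prob.sum(axis=-1, keepdims=True)
    return prob


def predict_volume(volume: Volume, checkpoints: Sequence, cfg: InferenceConfig,
                   plan: PreprocessPlan) -> tuple[ProbabilityGrid, LabelMap]:
    """Full prediction path: preprocess, sliding-window TTA ensemble, restore.

    ``checkpoints`` may be loaded networks or ``(network, meta)`` tuples.
    Returns the probability grid on the preprocessed grid and the argmax
    label map on the native grid.
    """
    networks = [c[0] if isinstance(c, tuple) else c for c in checkpoints]
    cfgs = [getattr(n, "config", None) for n in networks]
    if len({str(c) for c in cfgs}) > 1:
        raise ValueError("ensemble members have incompatible network configs")
    processed = preprocess_volume(volume, plan)
    prob = sliding_window_predict(processed.values, networks, cfg)
    grid = ProbabilityGrid(prob, processed.spacing,
                           provenance={"tta": cfg.tta, "n_members": len(networks),
                                       "window_size": list(cfg.window_size)})
    labels = prob.argmax(axis=-1).astype(np.uint8)  # ties break to lowest class
    pred = LabelMap(labels, processed.spacing, processed.origin, volume.scan_id)
    native = restore_to_original(pred, volume)
    return grid, native
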