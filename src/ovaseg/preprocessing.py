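"""Preprocessing: voxel-spacing resampling and grey-value Z-normalisation.

Volumes are resampled with centre-aligned linear interpolation, label
maps with nearest-neighbour lookup (so no interpolation-invented
classes), and intensities are Z-normalised per volume after optional
percentile clipping.  ``restore_to_original`` maps predictions back to
the native grid for volumetry.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import ndimage

from .volume_io import LabelMap, Volume, read_volume

__all__ = ["PreprocessPlan", "compute_target_spacing", "resample", "znormalize",
           "restore_to_original", "preprocess_volume"]

SD_FLOOR = 1e-8


class PreprocessPlan(BaseModel):
    model_config = ConfigDict(extra="forbid")

    target_spacing: tuple[float, float, float] = (5.0, 0.7, 0.7)
    #: intensity percentiles clipped before normalisation; None disables
    clip_percentiles: Optional[tuple[float, float]] = (0.5, 99.5)
    interp_order: int = 1  # trilinear for images; labels always nearest

    @model_validator(mode="after")
    def _valid(self):
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError(f"target spacing must be positive, got {self.target_spacing}")
        if self.clip_percentiles is not None:
            lo, hi = self.clip_percentiles
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"clip percentiles must satisfy 0 <= lo < hi <= 100, got {lo}, {hi}")
        return self

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.model_dump(), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "PreprocessPlan":
        return cls(**json.loads(Path(path).read_text()))


def compute_target_spacing(manifest: pd.DataFrame | Sequence) -> tuple[float, float, float]:
    """Per-axis median voxel spacing over the cohort.

    Accepts a manifest DataFrame (spacings read from the image headers) or
    a sequence of spacing triples / Volumes.
    """
    if isinstance(manifest, pd.DataFrame):
        if len(manifest) == 0:
            raise ValueError("empty manifest")
        spacings = [read_volume(p).spacing for p in manifest["image"]]
    else:
        spacings = [v.spacing if isinstance(v, (Volume, LabelMap)) else tuple(v)
                    for v in manifest]
        if not spacings:
            raise ValueError("empty spacing list")
    med = np.median(np.asarray(spacings, dtype=float), axis=0)
    return tuple(float(s) for s in med)


def _target_shape(shape, old_spacing, new_spacing):
    return tuple(max(1, int(round(n * o / t)))
                 for n, o, t in zip(shape, old_spacing, new_spacing))


def _centre_coords(new_shape, old_shape):
    """Per-axis source coordinates with voxel-centre alignment."""
    return [(np.arange(ns) + 0.5) * (os / ns) - 0.5 for ns, os in zip(new_shape, old_shape)]


def resample(obj: Volume | LabelMap, target_spacing, order: int = 1):
    """Resample to ``target_spacing``; returns the same kind as ``obj``.

    New shape per axis is ``round(old_shape * old_spacing / new_spacing)``
    (at least 1).  Label maps use nearest-neighbour lookup regardless of
    ``order``.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    is_labels = isinstance(obj, LabelMap)
    arr = obj.labels if is_labels else obj.values
    new_shape = _target_shape(arr.shape, obj.spacing, target_spacing)
    if new_shape == arr.shape and target_spacing == tuple(obj.spacing):
        out = arr.copy()
    else:
        axes = _centre_coords(new_shape, arr.shape)
        if is_labels:
            idx = [np.clip(np.round(c).astype(int), 0, n - 1)
                   for c, n in zip(axes, arr.shape)]
            out = arr[np.ix_(*idx)]
        else:
            grid = np.meshgrid(*axes, indexing="ij")
            out = ndimage.map_coordinates(
                arr.astype(np.float32), np.stack([g.ravel() for g in grid]),
                order=order, mode="nearest").reshape(new_shape)
    if is_labels:
        return LabelMap(out, target_spacing, obj.origin, obj.scan_id, dict(obj.label_names))
    return Volume(out, target_spacing, obj.origin, obj.scan_id)


def znormalize(v: Volume, plan: PreprocessPlan | None = None) -> Volume:
    """Clip to plan percentiles (if any) and Z-normalise to mean 0, sd 1.

    Constant volumes map to all zeros (standard-deviation floor) instead
    of raising, since cropped patches and phantoms can be constant.
    """
    plan = plan or PreprocessPlan()
    x = np.asarray(v.values, dtype=np.float32)
    if plan.clip_percentiles is not None:
        lo, hi = np.percentile(x, plan.clip_percentiles)
        x = np.clip(x, lo, hi)
    mu = float(x.mean())
    sd = float(x.std())
    if sd < SD_FLOOR:
        out = np.zeros_like(x)
    else:
        out = (x - mu) / sd
    return Volume(out, v.spacing, v.origin, v.scan_id)


def preprocess_volume(v: Volume, plan: PreprocessPlan) -> Volume:
    """Resample to the plan's target spacing, then Z-normalise."""
    return znormalize(resample(v, plan.target_spacing, order=plan.interp_order), plan)


def restore_to_original(pred: LabelMap, original: Volume | LabelMap) -> LabelMap:
    """Nearest-neighbour transfer of a predicted label map to the native grid."""
    exp_shape = _target_shape(original.shape, original.spacing, pred.spacing)
    if exp_shape != pred.shape:
        raise ValueError(
            f"prediction shape {pred.shape} does not match a resampling of the "
            f"original grid {original.shape} at spacing {pred.spacing} (expected {exp_shape})")
    axes = _centre_coords(original.shape, pred.shape)
    idx = [np.clip(np.round(c).astype(int), 0, n - 1)
           for c, n in zip(axes, pred.shape)]
    out = pred.labels[np.ix_(*idx)]
    return LabelMap(out, original.spacing, original.origin, pred.scan_id,
                    dict(pred.label_names))
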