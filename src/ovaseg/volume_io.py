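"""NIfTI volume / label-map IO with spacing metadata.

Internal convention: arrays are indexed ``(z, y, x)`` with ``spacing``
given in mm in the same order, so the (typically thick, ~5 mm) slice
axis is always axis 0.  NIfTI stores data ``(x, y, z)``; files are
transposed on read and restored on write.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

VALID_LABELS = (0, 1, 2)
LABEL_NAMES = {1: "pelvic/ovarian", 2: "omental"}

MANIFEST_COLUMNS = ["patient_id", "scan_id", "timepoint", "image", "label"]


@dataclasses.dataclass
class Volume:
    """A 3-D scalar grid (HU-like intensities) with physical metadata."""

    values: np.ndarray  # (z, y, x), float
    spacing: tuple[float, float, float]  # (z, y, x) voxel size in mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.values.ndim}")
        if any(n < 1 for n in self.values.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclasses.dataclass
class LabelMap:
    """Integer grid aligned to a :class:`Volume`.

    0 = background, 1 = pelvic/ovarian lesion, 2 = omental lesion.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scan_id: str = ""
    label_names: Mapping[int, str] = dataclasses.field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D label grid, got ndim={arr.ndim}")
        bad = np.setdiff1d(np.unique(arr), np.array(VALID_LABELS))
        if bad.size:
            raise ValueError(f"invalid label value(s) {bad.tolist()}; allowed: {list(VALID_LABELS)}")
        self.labels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _affine(spacing_zyx, origin_zyx) -> np.ndarray:
    # data stored (x, y, z) on disk -> diagonal affine in (x, y, z) order
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_zyx[2], spacing_zyx[1], spacing_zyx[0]
    aff[:3, 3] = origin_zyx[::-1]
    return aff


def _load(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return np.ascontiguousarray(data.transpose(2, 1, 0)), spacing, origin


def read_volume(path) -> Volume:
    """Read a NIfTI file as a :class:`Volume` in (z, y, x) order."""
    data, spacing, origin = _load(path)
    return Volume(data.astype(np.float32), spacing, origin, scan_id=Path(path).name.split(".")[0])


def read_labelmap(path) -> LabelMap:
    """Read a NIfTI label file; rejects labels outside {0, 1, 2}."""
    data, spacing, origin = _load(path)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label map contains non-integer values")
    return LabelMap(np.round(data).astype(np.int16), spacing, origin,
                    scan_id=Path(path).name.split(".")[0])


def write_volume(v: Volume, path) -> Path:
    """Write a volume as NIfTI (float32), (z, y, x) -> (x, y, z) on disk."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.values, dtype=np.float32).transpose(2, 1, 0),
                          _affine(v.spacing, v.origin))
    img.header.set_zooms((v.spacing[2], v.spacing[1], v.spacing[0]))
    nib.save(img, str(path))
    return path


def write_labelmap(m: LabelMap, path) -> Path:
    """Write a label map as unsigned 8-bit NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(m.labels.astype(np.uint8).transpose(2, 1, 0),
                          _affine(m.spacing, m.origin))
    img.header.set_zooms((m.spacing[2], m.spacing[1], m.spacing[0]))
    nib.save(img, str(path))
    return path


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV (patient_id, scan_id, timepoint, image, label)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    if df["scan_id"].duplicated().any():
        dup = df.loc[df["scan_id"].duplicated(), "scan_id"].tolist()
        raise ValueError(f"manifest contains duplicate scan_id(s): {dup}")
    bad_tp = sorted(set(df["timepoint"]) - {"pre", "post"})
    if bad_tp:
        raise ValueError(f"manifest timepoint(s) must be 'pre' or 'post', got {bad_tp}")
    return df[MANIFEST_COLUMNS]


def write_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path
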