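"""Seedable synthetic CT-like phantom cohorts with two lesion classes.

The generator emulates the cohort structure of multi-site ovarian cancer
CT: class 1 ("pelvic/ovarian") is bulky with few connected components,
class 2 ("omental") is a set of small deposits embedded in a fat-like
low-intensity band — the contrast that makes the omental site the harder
one and produces the classic fat-embedded false-positive failure mode.
Intensities are HU-like: soft tissue ~40, fat ~-100, lesions ~60, each
with voxelwise heterogeneity, plus additive acquisition noise.

Lesions are unions of random ellipsoids placed with a separation margin
and re-checked by 26-connectivity labelling, so the per-class component
count always lies in the configured range.  "post"-treatment scans of a
patient carry shrunken lesions (in-plane erosion plus random component
deletion), so per-class volume never exceeds the paired "pre" scan's.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import ndimage

from .volume_io import (LabelMap, Volume, write_labelmap, write_manifest, write_volume)

__all__ = ["PhantomConfig", "PhantomScan", "generate_phantom", "generate_cohort"]

CONN26 = np.ones((3, 3, 3), dtype=bool)


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    shape: tuple[int, int, int] = (24, 96, 96)
    spacing: tuple[float, float, float] = (5.0, 0.7, 0.7)  # mm, (z, y, x)

    soft_tissue_hu: tuple[float, float] = (40.0, 15.0)  # mean, spread
    fat_hu: tuple[float, float] = (-100.0, 15.0)
    lesion_hu: tuple[float, float] = (60.0, 10.0)
    noise_sd: float = 10.0  # additive acquisition noise, HU

    class1_count_range: tuple[int, int] = (1, 4)
    class1_semiaxes_mm: tuple[float, float] = (9.0, 15.0)
    class2_count_range: tuple[int, int] = (3, 10)
    class2_semiaxes_mm: tuple[float, float] = (4.0, 8.0)
    class2_present_prob: float = 1.0

    #: fat band position as fractions of the y extent (anterior wall)
    fat_band_y: tuple[float, float] = (0.10, 0.42)
    #: class-1 centre region as fractions of the y extent (pelvic soft tissue)
    class1_band_y: tuple[float, float] = (0.50, 0.92)

    seed: int = 0

    @model_validator(mode="after")
    def _valid(self):
        for name in ("class1_count_range", "class2_count_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be a non-empty range, got {(lo, hi)}")
        for name in ("class1_semiaxes_mm", "class2_semiaxes_mm"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive range, got {(lo, hi)}")
        if self.noise_sd < 0:
            raise ValueError("noise magnitude must be >= 0")
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        if 2 * self.class1_semiaxes_mm[1] > min(extent):
            raise ValueError(
                f"class-1 lesion scale {self.class1_semiaxes_mm[1]} mm exceeds grid "
                f"capacity (physical extent {extent} mm)")
        band = (self.fat_band_y[1] - self.fat_band_y[0]) * extent[1]
        if self.class2_count_range[1] > 0 and 2 * self.class2_semiaxes_mm[1] > max(band, 1e-9) * 1.5:
            raise ValueError(
                f"class-2 lesion scale {self.class2_semiaxes_mm[1]} mm exceeds the "
                f"fat band capacity ({band:.1f} mm)")
        return self

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclasses.dataclass
class PhantomScan:
    volume: Volume
    labels: LabelMap
    summary: dict  # {class: {"volume_cm3": ..., "n_components": ...}}


def _summarise(labels: LabelMap) -> dict:
    voxel_cm3 = float(np.prod(labels.spacing)) / 1000.0
    out = {}
    for c in (1, 2):
        mask = labels.labels == c
        _, n = ndimage.label(mask, structure=CONN26)
        out[c] = {"volume_cm3": float(mask.sum()) * voxel_cm3, "n_components": int(n)}
    return out


def _tissue_field(shape, sd, rng) -> np.ndarray:
    """Zero-mean voxelwise tissue heterogeneity of sd ``sd``."""
    return sd * rng.standard_normal(shape)


def _place_ellipsoids(rng, k, semi_range, z_lim, y_lim, x_lim, max_tries=400):
    """Sample up to k non-touching ellipsoids (centre mm, semi-axes mm)."""
    placed = []
    gap = 10.0  # mm: > 2 voxel diagonals at 5 mm slices, prevents 26-conn merging
    for _ in range(k):
        ok = False
        for _ in range(max_tries):
            semi = rng.uniform(semi_range[0], semi_range[1], size=3)
            lims = []
            feasible = True
            for (lo, hi), s in zip((z_lim, y_lim, x_lim), semi):
                clo, chi = lo + s, hi - s
                if clo > chi:
                    clo = chi = 0.5 * (lo + hi)
                    if hi - lo < 1.2 * s:  # cannot even centre it
                        feasible = False
                lims.append((clo, chi))
            if not feasible:
                continue
            centre = np.array([rng.uniform(lo, hi) for lo, hi in lims])
            if all(np.linalg.norm(centre - c0) > semi.max() + s0.max() + gap
                   for c0, s0 in placed):
                placed.append((centre, semi))
                ok = True
                break
        if not ok:
            break
    return placed


def _rasterise(shape, spacing, ellipsoids) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    for centre, semi in ellipsoids:
        # bounding box in voxels
        sl = []
        for ax in range(3):
            lo = int(np.floor((centre[ax] - semi[ax]) / spacing[ax])) - 1
            hi = int(np.ceil((centre[ax] + semi[ax]) / spacing[ax])) + 1
            sl.append(slice(max(lo, 0), min(hi, shape[ax])))
        zz, yy, xx = np.meshgrid(coords[0][sl[0]], coords[1][sl[1]], coords[2][sl[2]],
                                 indexing="ij")
        d = (((zz - centre[0]) / semi[0]) ** 2 + ((yy - centre[1]) / semi[1]) ** 2
             + ((xx - centre[2]) / semi[2]) ** 2)
        mask[sl[0], sl[1], sl[2]] |= d <= 1.0
    return mask


def _place_labels(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    ez, ey, ex = cfg.extent_mm()
    labels = np.zeros(cfg.shape, dtype=np.uint8)

    lo1, hi1 = cfg.class1_count_range
    k1 = int(rng.integers(lo1, hi1 + 1)) if hi1 > 0 else 0
    ell1 = _place_ellipsoids(rng, k1, cfg.class1_semiaxes_mm,
                             (0.0, ez),
                             (cfg.class1_band_y[0] * ey, cfg.class1_band_y[1] * ey),
                             (0.08 * ex, 0.92 * ex))
    labels[_rasterise(cfg.shape, cfg.spacing, ell1)] = 1

    lo2, hi2 = cfg.class2_count_range
    k2 = 0
    if hi2 > 0 and rng.uniform() < cfg.class2_present_prob:
        k2 = int(rng.integers(lo2, hi2 + 1))
    ell2 = _place_ellipsoids(rng, k2, cfg.class2_semiaxes_mm,
                             (0.0, ez),
                             (cfg.fat_band_y[0] * ey, cfg.fat_band_y[1] * ey),
                             (0.05 * ex, 0.95 * ex))
    m2 = _rasterise(cfg.shape, cfg.spacing, ell2)
    labels[m2 & (labels == 0)] = 2
    return labels


def _render(cfg: PhantomConfig, rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    """HU-like intensity volume for a given label grid."""
    sp = cfg.spacing
    vol = cfg.soft_tissue_hu[0] + _tissue_field(cfg.shape, cfg.soft_tissue_hu[1], rng)
    ey = cfg.extent_mm()[1]
    ys = (np.arange(cfg.shape[1]) + 0.5) * sp[1]
    band = (ys >= cfg.fat_band_y[0] * ey) & (ys < cfg.fat_band_y[1] * ey)
    fat = cfg.fat_hu[0] + _tissue_field(cfg.shape, cfg.fat_hu[1], rng)
    vol[:, band, :] = fat[:, band, :]
    lesion = cfg.lesion_hu[0] + _tissue_field(cfg.shape, cfg.lesion_hu[1], rng)
    fg = labels > 0
    vol[fg] = lesion[fg]
    if cfg.noise_sd > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
    return vol.astype(np.float32)


def _counts_in_range(labels: np.ndarray, cfg: PhantomConfig) -> bool:
    for c, (lo, hi) in ((1, cfg.class1_count_range), (2, cfg.class2_count_range)):
        _, n = ndimage.label(labels == c, structure=CONN26)
        if n > hi:
            return False
        if n < lo and not (c == 2 and cfg.class2_present_prob < 1.0):
            return False
    return True


def generate_phantom(config: PhantomConfig, rng: Optional[np.random.Generator] = None,
                     scan_id: str = "phantom") -> PhantomScan:
    """Generate one phantom scan; identical config (and seed) => identical output."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    for _ in range(5):
        sub = np.random.default_rng(rng.integers(0, 2 ** 31))
        labels = _place_labels(config, sub)
        if _counts_in_range(labels, config):
            break
    else:
        raise RuntimeError("could not realise the configured component count ranges; "
                           "lesion scale likely exceeds grid capacity")
    vol = _render(config, sub, labels)
    volume = Volume(vol, config.spacing, scan_id=scan_id)
    labelmap = LabelMap(labels, config.spacing, scan_id=scan_id)
    return PhantomScan(volume, labelmap, _summarise(labelmap))


def _shrink(labels: np.ndarray, rng: np.random.Generator,
            p_delete: float = 0.35) -> np.ndarray:
    """Treatment response: in-plane erosion plus random component deletion."""
    out = np.zeros_like(labels)
    cross = np.zeros((1, 3, 3), dtype=bool)
    cross[0, 1, :] = cross[0, :, 1] = True
    for c in (1, 2):
        mask = labels == c
        comp, n = ndimage.label(mask, structure=CONN26)
        keep = np.zeros_like(mask)
        for i in range(1, n + 1):
            if rng.uniform() < p_delete:
                continue
            keep |= comp == i
        keep = ndimage.binary_erosion(keep, structure=cross)
        out[keep] = c
    return out


def generate_cohort(n_patients: int, scans_per_patient: int, config: PhantomConfig,
                    seed: int, out_dir) -> pd.DataFrame:
    """Write a phantom cohort (NIfTI pairs, manifest.csv, ground_truth.json).

    The first scan of each patient is the "pre" timepoint; subsequent
    scans are "post" with monotonically shrinking lesions.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, truth = [], {}
    root = np.random.default_rng(seed)
    for p in range(n_patients):
        pid = f"P{p:03d}"
        prng = np.random.default_rng(root.integers(0, 2 ** 31))
        scan = generate_phantom(config, rng=prng, scan_id=f"{pid}_pre")
        cur_labels = scan.labels.labels
        for t in range(scans_per_patient):
            if t == 0:
                timepoint, sid = "pre", f"{pid}_pre"
                vol, lab = scan.volume, scan.labels
            else:
                timepoint, sid = "post", f"{pid}_post{t}"
                cur_labels = _shrink(cur_labels, prng)
                lab = LabelMap(cur_labels, config.spacing, scan_id=sid)
                vol = Volume(_render(config, prng, cur_labels), config.spacing, scan_id=sid)
            img_path = out_dir / f"{sid}_image.nii.gz"
            lab_path = out_dir / f"{sid}_label.nii.gz"
            write_volume(vol, img_path)
            write_labelmap(lab, lab_path)
            truth[sid] = {str(k): v for k, v in _summarise(lab).items()}
            rows.append({"patient_id": pid, "scan_id": sid, "timepoint": timepoint,
                         "image": str(img_path), "label": str(lab_path)})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest
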