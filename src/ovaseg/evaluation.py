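"""Segmentation metrics and cohort statistics.

Per-site Dice (0-100 scale), sensitivity/precision, physical volume,
26-connected component counts, cross-site label confusion, Bland-Altman
volume agreement, an exact paired Wilcoxon signed-rank test, and the
site-filtered cohort aggregation rule: every metric is computed only on
scans whose ground truth contains the corresponding site.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume_io import LabelMap, read_labelmap, read_manifest

__all__ = ["dice", "sensitivity_precision", "volume_cm3", "component_count",
           "cross_site_confusion", "bland_altman", "wilcoxon_paired",
           "scan_metrics", "cohort_report", "compare_methods"]

SITES = (1, 2)
SITE_NAMES = {1: "pelvic_ovarian", 2: "omental"}


def _masks(pred: LabelMap | np.ndarray, gt: LabelMap | np.ndarray, site: int):
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    g = gt.labels if isinstance(gt, LabelMap) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"misaligned grids: {p.shape} vs {g.shape}")
    return p == site, g == site


def dice(pred, gt, site: int) -> float:
    """Dice similarity coefficient of one site, in percent."""
    p, g = _masks(pred, gt, site)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return float("nan")
    return 100.0 * 2.0 * int((p & g).sum()) / denom


def sensitivity_precision(pred, gt, site: int) -> tuple[float, float]:
    """(sensitivity, precision) of one site, in percent.

    Precision is NaN when the prediction contains no voxel of the site.
    """
    p, g = _masks(pred, gt, site)
    tp = int((p & g).sum())
    sens = 100.0 * tp / int(g.sum()) if g.any() else float("nan")
    prec = 100.0 * tp / int(p.sum()) if p.any() else float("nan")
    return sens, prec


def volume_cm3(mask: LabelMap, site: int) -> float:
    """Physical volume of one site in cm^3 (voxel count x voxel volume)."""
    n = int((mask.labels == site).sum())
    return n * float(np.prod(mask.spacing)) / 1000.0


CONN = {6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3)}


def component_count(mask, site: int, connectivity: int = 26) -> int:
    """Number of connected components of one site (26-connectivity default)."""
    m = mask.labels if isinstance(mask, LabelMap) else np.asarray(mask)
    _, n = ndimage.label(m == site, structure=CONN[connectivity])
    return int(n)


def cross_site_confusion(pred, gt) -> dict[tuple[int, int], bool]:
    """Per ordered site pair (a, b): does any ground-truth voxel of a
    carry predicted label b?"""
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    g = gt.labels if isinstance(gt, LabelMap) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"misaligned grids: {p.shape} vs {g.shape}")
    out = {}
    for a in SITES:
        for b in SITES:
            if a == b:
                continue
            out[(a, b)] = bool(((g == a) & (p == b)).any())
    return out


def bland_altman(gt_volumes: Sequence[float], pred_volumes: Sequence[float]):
    """Agreement of paired volumes: (bias, (lower, upper) limits).

    Differences are ground truth minus prediction, so systematic
    under-segmentation gives a positive bias.  Limits are
    bias +/- 1.96 * sd (sample sd, ddof=1).
    """
    g = np.asarray(gt_volumes, dtype=float)
    p = np.asarray(pred_volumes, dtype=float)
    if g.shape != p.shape or g.ndim != 1 or len(g) < 2:
        raise ValueError("need two equal-length lists with n >= 2")
    if not (np.isfinite(g).all() and np.isfinite(p).all()):
        raise ValueError("volumes must be finite")
    d = g - p
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def _signed_rank_exact_p(r2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic via the
    generating-polynomial distribution (handles midranks; ranks doubled
    to integers)."""
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    lo = counts[:w2i + 1].sum()
    hi = counts[w2i:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_paired(a: Sequence[float], b: Sequence[float],
                    exact_max_n: int = 25) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic signed-rank).  The null
    distribution is enumerated exactly for n_effective <= ``exact_max_n``
    (midranks supported); larger samples use the normal approximation
    with tie correction.  Returns (statistic W, p, n_effective); the
    degenerate all-zero case returns (0.0, 1.0, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired lists must be 1-D and equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        r2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(r2, 2 * w)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w, p, n


# --------------------------------------------------------------------------
# cohort-level reporting

def scan_metrics(pred: LabelMap, gt: LabelMap, connectivity: int = 26) -> dict:
    """One metrics row; site metrics are None when the site is absent
    from the ground truth (the site-filtering rule)."""
    row = {"scan_id": gt.scan_id or pred.scan_id}
    for s in SITES:
        name = SITE_NAMES[s]
        present = bool((gt.labels == s).any())
        row[f"{name}_present"] = present
        row[f"{name}_gt_volume_cm3"] = volume_cm3(gt, s)
        row[f"{name}_pred_volume_cm3"] = volume_cm3(pred, s)
        row[f"{name}_gt_components"] = component_count(gt, s, connectivity)
        row[f"{name}_pred_components"] = component_count(pred, s, connectivity)
        if present:
            sens, prec = sensitivity_precision(pred, gt, s)
            row[f"{name}_dsc"] = dice(pred, gt, s)
            row[f"{name}_sensitivity"] = sens
            row[f"{name}_precision"] = prec
        else:
            row[f"{name}_dsc"] = row[f"{name}_sensitivity"] = row[f"{name}_precision"] = None
    conf = cross_site_confusion(pred, gt)
    row["confusion_1_as_2"] = conf[(1, 2)]
    row["confusion_2_as_1"] = conf[(2, 1)]
    return row


def _aggregate(per_scan: pd.DataFrame, connectivity: int = 26) -> dict:
    report: dict = {"n_scans": int(len(per_scan)), "sites": {}}
    for s in SITES:
        name = SITE_NAMES[s]
        sub = per_scan[per_scan[f"{name}_present"].astype(bool)]
        sec: dict = {"n": int(len(sub))}
        for metric in ("dsc", "sensitivity", "precision"):
            vals = pd.to_numeric(sub[f"{name}_{metric}"], errors="coerce").dropna()
            sec[metric] = {
                "mean": float(vals.mean()) if len(vals) else None,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
                "formatted": (f"{vals.mean():.0f} ± {vals.std(ddof=1):.0f}"
                              if len(vals) > 1 else None),
                "n": int(len(vals)),
            }
        if len(sub) >= 2:
            bias, (lo, hi) = bland_altman(sub[f"{name}_gt_volume_cm3"],
                                          sub[f"{name}_pred_volume_cm3"])
            sec["bland_altman"] = {"bias_cm3": bias, "loa_lower": lo, "loa_upper": hi,
                                   "n": int(len(sub))}
        # confusion: scans containing site s where any of its gt voxels got the other label
        conf_col = "confusion_1_as_2" if s == 1 else "confusion_2_as_1"
        sec["cross_site_confusion"] = {"n_flagged": int(sub[conf_col].astype(bool).sum()),
                                       "n": int(len(sub))}
        # outlier slices: bottom-quartile DSC vs volume
        dscs = pd.to_numeric(sub[f"{name}_dsc"], errors="coerce")
        vols = pd.to_numeric(sub[f"{name}_gt_volume_cm3"], errors="coerce")
        if len(sub) >= 4:
            low_dsc = sub[dscs <= dscs.quantile(0.25)]
            low_vol = sub[vols <= vols.quantile(0.25)]
            sec["bottom_quartile_dsc"] = {
                "n": int(len(low_dsc)),
                "median_volume_cm3": float(pd.to_numeric(
                    low_dsc[f"{name}_gt_volume_cm3"]).median()),
                "full_set_median_volume_cm3": float(vols.median()),
            }
            sec["bottom_quartile_volume"] = {
                "n": int(len(low_vol)),
                "mean_dsc": float(pd.to_numeric(low_vol[f"{name}_dsc"]).mean()),
                "full_set_mean_dsc": float(dscs.mean()),
            }
        report["sites"][name] = sec
    return report


def cohort_report(manifest: pd.DataFrame | str, pred_dir, gt_dir=None,
                  connectivity: int = 26, out_dir=None):
    """Evaluate a cohort: per-scan metrics plus site-filtered aggregates.

    Predictions are ``{scan_id}.nii.gz`` under ``pred_dir``; ground truth
    comes from the manifest's label column (or ``gt_dir`` with the same
    naming).  Returns ``(report dict, per-scan DataFrame)`` and writes
    CSV/JSON artifacts when ``out_dir`` is given.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    pred_dir = Path(pred_dir)
    missing = []
    for row in manifest.itertuples():
        if not (pred_dir / f"{row.scan_id}.nii.gz").exists():
            missing.append(f"prediction {pred_dir / (row.scan_id + '.nii.gz')}")
        gt_path = Path(gt_dir) / f"{row.scan_id}.nii.gz" if gt_dir else Path(row.label)
        if not gt_path.exists():
            missing.append(f"ground truth {gt_path}")
    if missing:
        raise FileNotFoundError("missing files:\n  " + "\n  ".join(missing))

    rows = []
    for row in manifest.itertuples():
        pred = read_labelmap(pred_dir / f"{row.scan_id}.nii.gz")
        gt_path = Path(gt_dir) / f"{row.scan_id}.nii.gz" if gt_dir else Path(row.label)
        gt = read_labelmap(gt_path)
        gt.scan_id = row.scan_id
        m = scan_metrics(pred, gt, connectivity)
        m["patient_id"] = row.patient_id
        m["timepoint"] = row.timepoint
        rows.append(m)
    per_scan = pd.DataFrame(rows)
    report = _aggregate(per_scan, connectivity)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_scan.to_csv(out_dir / "per_scan_metrics.csv", index=False)
        (out_dir / "aggregate.json").write_text(json.dumps(report, indent=1))
        ba_rows = []
        for s in SITES:
            name = SITE_NAMES[s]
            sub = per_scan[per_scan[f"{name}_present"].astype(bool)]
            for r in sub.itertuples():
                gt_v = getattr(r, f"{name}_gt_volume_cm3")
                pr_v = getattr(r, f"{name}_pred_volume_cm3")
                ba_rows.append({"scan_id": r.scan_id, "site": name,
                                "mean_cm3": 0.5 * (gt_v + pr_v),
                                "difference_cm3": gt_v - pr_v})
        pd.DataFrame(ba_rows).to_csv(out_dir / "bland_altman.csv", index=False)
    return report, per_scan


def compare_methods(per_scan_a: pd.DataFrame, per_scan_b: pd.DataFrame) -> dict:
    """Paired Wilcoxon comparison of two methods' per-scan DSC, per site."""
    out = {}
    merged = per_scan_a.merge(per_scan_b, on="scan_id", suffixes=("_a", "_b"))
    for s in SITES:
        name = SITE_NAMES[s]
        sub = merged.dropna(subset=[f"{name}_dsc_a", f"{name}_dsc_b"])
        if len(sub) == 0:
            out[name] = {"statistic": None, "p": None, "n": 0}
            continue
        w, p, n = wilcoxon_paired(sub[f"{name}_dsc_a"], sub[f"{name}_dsc_b"])
        out[name] = {"statistic": w, "p": p, "n": n}
    return out
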