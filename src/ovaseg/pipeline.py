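"""Staged experiment pipeline: phantom -> preprocess -> train -> predict -> evaluate.

Every stage is also exposed as a CLI subcommand; ``run_all`` chains them
under one output directory, writes a resolved-config snapshot and a
line-delimited JSON log with the seeds in use, and is deterministic in
the experiment seed.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, volume_io
from .config import ExperimentConfig
from .evaluation import cohort_report
from .inference import predict_volume
from .phantom import generate_cohort
from .preprocessing import compute_target_spacing
from .training import load_checkpoint, train

__all__ = ["run_all", "run_stage", "split_cohort"]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self._f = path.open("a")

    def event(self, stage: str, **kw) -> None:
        rec = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, **kw}
        self._f.write(json.dumps(rec) + "\n")
        self._f.flush()

    def close(self):
        self._f.close()


def _derived_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    phantom_seed, train_seed = [int(s) for s in ss.generate_state(2) % (2 ** 31)]
    return {"phantom": phantom_seed, "train": train_seed}


def split_cohort(manifest: pd.DataFrame, n_test_patients: int):
    """Deterministic patient-level train/test split (last patients by id)."""
    patients = sorted(manifest["patient_id"].unique())
    if n_test_patients >= len(patients):
        raise ValueError("n_test_patients must leave at least one training patient")
    test = set(patients[len(patients) - n_test_patients:])
    return (manifest[~manifest["patient_id"].isin(test)].reset_index(drop=True),
            manifest[manifest["patient_id"].isin(test)].reset_index(drop=True))


def _stage_phantom(cfg: ExperimentConfig, out: Path, seeds, log) -> pd.DataFrame:
    pdir = out / "phantom"
    manifest = generate_cohort(cfg.phantom.n_patients, cfg.phantom.scans_per_patient,
                               cfg.phantom.phantom, seeds["phantom"], pdir)
    log.event("phantom", n_scans=len(manifest), seed=seeds["phantom"], dir=str(pdir))
    return manifest


def _manifest(out: Path) -> pd.DataFrame:
    p = out / "phantom" / "manifest.csv"
    if not p.exists():
        raise FileNotFoundError(f"pipeline state incomplete: {p} missing "
                                "(run the phantom stage first)")
    return volume_io.read_manifest(p)


def _stage_train(cfg: ExperimentConfig, out: Path, seeds, log) -> dict:
    manifest = _manifest(out)
    train_manifest, _ = split_cohort(manifest, cfg.phantom.n_test_patients)
    tcfg = cfg.train.model_copy(update={"seed": seeds["train"]})
    net_cfg = cfg.network.model_copy(update={"spacing": cfg.preprocess.target_spacing})
    result = train(train_manifest, net_cfg, tcfg, cfg.mode, plan=cfg.preprocess,
                   aug_cfg=cfg.augment, out_dir=out / "models",
                   inference_cfg=cfg.inference)
    log.event("train", mode=cfg.mode, seed=seeds["train"],
              checkpoints=[str(p) for p in result["checkpoints"]])
    return result


def _stage_predict(cfg: ExperimentConfig, out: Path, log) -> Path:
    manifest = _manifest(out)
    _, test_manifest = split_cohort(manifest, cfg.phantom.n_test_patients)
    model_dir = out / "models"
    ckpts = sorted(model_dir.glob("model*.npz")) or sorted(model_dir.glob("fold*.npz"))
    if not ckpts:
        raise FileNotFoundError(f"pipeline state incomplete: no checkpoints in {model_dir}")
    nets = [load_checkpoint(p)[0] for p in ckpts]
    pred_dir = out / "predictions"
    pred_dir.mkdir(exist_ok=True)
    for row in test_manifest.itertuples():
        vol = volume_io.read_volume(row.image)
        _, labels = predict_volume(vol, nets, cfg.inference, cfg.preprocess)
        labels.scan_id = row.scan_id
        volume_io.write_labelmap(labels, pred_dir / f"{row.scan_id}.nii.gz")
    log.event("predict", n_scans=len(test_manifest), n_members=len(nets),
              tta=cfg.inference.tta, dir=str(pred_dir))
    return pred_dir


def _stage_evaluate(cfg: ExperimentConfig, out: Path, log):
    manifest = _manifest(out)
    if cfg.mode == "cv":
        eval_manifest, _ = split_cohort(manifest, cfg.phantom.n_test_patients)
        pred_dir = out / "models" / "oof_predictions"
    else:
        _, eval_manifest = split_cohort(manifest, cfg.phantom.n_test_patients)
        pred_dir = out / "predictions"
    report, per_scan = cohort_report(eval_manifest, pred_dir,
                                     connectivity=cfg.evaluate.connectivity,
                                     out_dir=out / "report")
    log.event("evaluate", n_scans=len(per_scan), report=str(out / "report"))
    return report, per_scan


def run_stage(command: str, cfg: ExperimentConfig, out_dir=None):
    """Run one pipeline stage (or ``all``) under ``out_dir``."""
    out = Path(out_dir) if out_dir else Path(cfg.out_root) / cfg.name
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(cfg.seed)
    log = _RunLog(out / "run_log.jsonl")
    (out / "resolved_config.yaml").write_text(cfg.resolved_yaml())
    log.event("start", command=command, seed=cfg.seed, derived_seeds=seeds,
              version=__version__, python=platform.python_version())
    try:
        result = None
        if command in ("phantom", "all"):
            result = _stage_phantom(cfg, out, seeds, log)
        if command in ("preprocess",):
            # standalone spacing planning for an existing cohort
            manifest = _manifest(out)
            spacing = compute_target_spacing(manifest)
            log.event("preprocess", median_spacing=list(spacing))
            result = spacing
        if command in ("train", "all"):
            result = _stage_train(cfg, out, seeds, log)
        if command in ("predict", "all") and cfg.mode == "full":
            result = _stage_predict(cfg, out, log)
        if command in ("evaluate", "all"):
            result = _stage_evaluate(cfg, out, log)
        log.event("done", command=command)
        return result
    finally:
        log.close()


def run_all(cfg: ExperimentConfig, out_dir=None):
    """Phantom -> preprocess -> train -> predict -> evaluate; returns
    (report, per-scan DataFrame)."""
    return run_stage("all", cfg, out_dir)
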