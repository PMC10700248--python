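"""Experiment configuration: one YAML file wiring every pipeline stage.

Every block is validated against its module's config type before any
stage runs; unknown keys are rejected by name.  Presets live inside the
package (``tiny`` for CPU-scale phantom experiments, ``paper_model`` and
``nnunet_baseline`` transcribing the two full-scale recipes), so the
tuned-model-vs-baseline comparison is a config diff.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .augmentation import AugmentConfig
from .inference import InferenceConfig
from .network import NetworkConfig
from .phantom import PhantomConfig
from .preprocessing import PreprocessPlan
from .training import TrainConfig

__all__ = ["ExperimentConfig", "CohortSpec", "EvaluateConfig", "ConfigError",
           "load_config", "preset_path"]


class ConfigError(ValueError):
    """Invalid experiment configuration (all violations listed)."""


class CohortSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_patients: int = 10
    scans_per_patient: int = 2
    #: patients held out as the test split (their scans are never trained on)
    n_test_patients: int = 2
    phantom: PhantomConfig = PhantomConfig()


class EvaluateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    connectivity: Literal[6, 18, 26] = 26


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "experiment"
    seed: int = 0
    out_root: str = "./runs"
    mode: Literal["full", "cv"] = "full"
    phantom: CohortSpec = CohortSpec()
    preprocess: PreprocessPlan = PreprocessPlan()
    network: NetworkConfig = NetworkConfig()
    augment: AugmentConfig = AugmentConfig()
    train: TrainConfig = TrainConfig()
    inference: InferenceConfig = InferenceConfig()
    evaluate: EvaluateConfig = EvaluateConfig()

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def preset_path(name: str) -> Path:
    """Path of a packaged preset (``tiny``, ``paper_model``, ``nnunet_baseline``)."""
    base = Path(str(resources.files("ovaseg") / "presets"))
    p = base / (name if name.endswith(".yaml") else f"{name}.yaml")
    if not p.exists():
        avail = sorted(f.stem for f in base.glob("*.yaml"))
        raise ConfigError(f"unknown preset {name!r}; available: {avail}")
    return p


def _resolve_config_path(path: str) -> Path:
    p = Path(path)
    if p.exists():
        return p
    # allow e.g. "presets/tiny.yaml" or "tiny" to mean the packaged preset
    return preset_path(Path(path).name)


def _deep_set(d: dict, dotted: str, value) -> None:
    keys = dotted.split(".")
    cur = d
    for k in keys[:-1]:
        cur = cur.setdefault(k, {})
        if not isinstance(cur, dict):
            raise ConfigError(f"override {dotted!r}: {k!r} is not a mapping")
    cur[keys[-1]] = value


def load_config(path: str, overrides: Optional[list[str]] = None) -> ExperimentConfig:
    """Load and validate an experiment YAML, applying dotted-path overrides
    (``train.total_steps=200``).  Raises :class:`ConfigError` listing every
    violation."""
    p = _resolve_config_path(path)
    try:
        raw = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {p}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    raw = copy.deepcopy(raw)
    for ov in overrides or []:
        if "=" not in ov:
            raise ConfigError(f"override {ov!r} must look like key.path=value")
        key, _, val = ov.partition("=")
        _deep_set(raw, key.strip(), yaml.safe_load(val))
    try:
        return ExperimentConfig(**raw)
    except ValidationError as e:
        lines = []
        for err in e.errors():
            loc = ".".join(str(x) for x in err["loc"])
            lines.append(f"  {loc}: {err['msg']}")
        raise ConfigError(f"invalid configuration ({p}):\n" + "\n".join(lines)) from e
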