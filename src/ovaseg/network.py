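"""Segmentation network architectures.

Two variants share one training/inference code path:

* ``resnet_unet`` — a four-stage U-Net whose encoder is a residual
  network with 1, 2, 6 and 3 residual blocks per stage and 32 first-stage
  filters doubling at each stage (the tuned model);
* ``baseline_unet`` — a plain six-stage U-Net with two
  conv→instance-norm→LReLU blocks per stage (the self-configuring
  framework's suggested configuration).

Both use instance normalisation, leaky rectifiers, stride-2 convolutions
for downsampling (stride (1,2,2) while the slice spacing is more than
2.5x the in-plane spacing, so thick-slice CT is not collapsed along z
prematurely), transposed-convolution upsampling, concatenation skips and
optional deep supervision.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import _nn

__all__ = ["NetworkConfig", "SegNetwork", "build_network", "softmax_probabilities",
           "plan_strides"]


def plan_strides(spacing, n_stages) -> list[tuple[int, int, int]]:
    """Per-transition downsampling strides adapted to voxel anisotropy.

    An axis is left un-downsampled in a transition while its current
    spacing exceeds 2.5x the finest current spacing.
    """
    sp = np.asarray(spacing, dtype=float)
    strides = []
    for _ in range(n_stages - 1):
        s = np.where(sp > 2.5 * sp.min(), 1, 2)
        if s.max() == 1:  # pathological config; still downsample somewhere
            s[:] = 2
        strides.append(tuple(int(v) for v in s))
        sp = sp * s
    return strides


class NetworkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variant: Literal["resnet_unet", "baseline_unet"] = "resnet_unet"
    n_stages: int = 4
    blocks_per_stage: tuple[int, ...] = (1, 2, 6, 3)
    base_filters: int = 32
    max_filters: int = 320
    in_channels: int = 1
    n_classes: int = 3
    leaky_slope: float = 0.01
    deep_supervision: bool = True
    # spacing of the preprocessed data, used to plan strides if none given
    spacing: tuple[float, float, float] = (5.0, 0.7, 0.7)
    strides: Optional[tuple[tuple[int, int, int], ...]] = None

    @field_validator("base_filters")
    @classmethod
    def _filters(cls, v):
        if v < 1:
            raise ValueError("base_filters must be >= 1")
        return v

    @field_validator("n_classes")
    @classmethod
    def _classes(cls, v):
        if v < 2:
            raise ValueError("n_classes must be >= 2")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if len(self.blocks_per_stage) != self.n_stages:
            raise ValueError(
                f"blocks_per_stage has {len(self.blocks_per_stage)} entries "
                f"for n_stages={self.n_stages}")
        if self.strides is not None and len(self.strides) != self.n_stages - 1:
            raise ValueError("strides must have n_stages - 1 entries")
        return self

    @classmethod
    def baseline(cls, **over) -> "NetworkConfig":
        """The suggested six-stage plain U-Net configuration."""
        kw = dict(variant="baseline_unet", n_stages=6, blocks_per_stage=(2,) * 6)
        kw.update(over)
        return cls(**kw)

    def stage_filters(self) -> list[int]:
        return [min(self.base_filters * 2 ** i, self.max_filters)
                for i in range(self.n_stages)]

    def transition_strides(self) -> list[tuple[int, int, int]]:
        if self.strides is not None:
            return [tuple(s) for s in self.strides]
        return plan_strides(self.spacing, self.n_stages)

    def patch_divisor(self) -> tuple[int, int, int]:
        div = np.ones(3, dtype=int)
        for s in self.transition_strides():
            div *= s
        return tuple(int(v) for v in div)


class _ResBlock(_nn.Layer):
    """conv-IN-LReLU-conv-IN plus identity/projection shortcut, then LReLU."""

    def __init__(self, c_in, c_out, stride, slope, *, rng, dtype, name):
        self.conv1 = _nn.Conv3d(c_in, c_out, stride=stride, rng=rng, dtype=dtype, name=f"{name}.c1")
        self.in1 = _nn.InstanceNorm(c_out, dtype=dtype, name=f"{name}.n1")
        self.act1 = _nn.LeakyReLU(slope)
        self.conv2 = _nn.Conv3d(c_out, c_out, rng=rng, dtype=dtype, name=f"{name}.c2")
        self.in2 = _nn.InstanceNorm(c_out, dtype=dtype, name=f"{name}.n2")
        self.act_out = _nn.LeakyReLU(slope)
        self.proj = None
        if c_in != c_out or tuple(stride) != (1, 1, 1):
            self.proj = _nn.Sequential([
                _nn.Conv3d(c_in, c_out, ksize=(1, 1, 1), stride=stride,
                           rng=rng, dtype=dtype, name=f"{name}.proj"),
                _nn.InstanceNorm(c_out, dtype=dtype, name=f"{name}.projn"),
            ])

    def params(self):
        ps = self.conv1.params() + self.in1.params() + self.conv2.params() + self.in2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x):
        h = self.act1.forward(self.in1.forward(self.conv1.forward(x)))
        h = self.in2.forward(self.conv2.forward(h))
        sc = x if self.proj is None else self.proj.forward(x)
        return self.act_out.forward(h + sc)

    def backward(self, dy):
        dy = self.act_out.backward(dy)
        dsc = dy if self.proj is None else self.proj.backward(dy)
        dh = self.in2.backward(dy)
        dh = self.conv2.backward(dh)
        dh = self.act1.backward(dh)
        dh = self.in1.backward(dh)
        dx = self.conv1.backward(dh)
        return dx + dsc


class _PlainBlock(_nn.Layer):
    """conv-IN-LReLU."""

    def __init__(self, c_in, c_out, stride, slope, *, rng, dtype, name):
        self.seq = _nn.Sequential([
            _nn.Conv3d(c_in, c_out, stride=stride, rng=rng, dtype=dtype, name=name),
            _nn.InstanceNorm(c_out, dtype=dtype, name=f"{name}.n"),
            _nn.LeakyReLU(slope),
        ])

    def params(self):
        return self.seq.params()

    def forward(self, x):
        return self.seq.forward(x)

    def backward(self, dy):
        return self.seq.backward(dy)


class SegNetwork:
    """Encoder-decoder segmentation network built from :class:`NetworkConfig`.

    ``forward(x, train=True)`` returns ``{level: scores}`` for the deep
    supervision levels (level 0 is full resolution); in eval mode, or with
    deep supervision off, only level 0 is produced.  ``backward`` takes the
    matching ``{level: dscores}``.  ``__call__`` is the plain eval path
    returning full-resolution scores, the interface inference relies on.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        cf = config.stage_filters()
        strides = config.transition_strides()
        slope = config.leaky_slope
        block = _ResBlock if config.variant == "resnet_unet" else _PlainBlock

        self.encoder: list[list[_nn.Layer]] = []
        c_prev = config.in_channels
        for i in range(config.n_stages):
            stage = []
            for b in range(config.blocks_per_stage[i]):
                stride = strides[i - 1] if (i > 0 and b == 0) else (1, 1, 1)
                stage.append(block(c_prev, cf[i], stride, slope, rng=rng,
                                   dtype=dtype, name=f"enc{i}.{b}"))
                c_prev = cf[i]
            self.encoder.append(stage)

        self.up: list[_nn.Layer] = []
        self.dec: list[_nn.Layer] = []
        for lvl in range(config.n_stages - 1):
            self.up.append(_nn.ConvTranspose3d(cf[lvl + 1], cf[lvl], stride=strides[lvl],
                                               rng=rng, dtype=dtype, name=f"up{lvl}"))
            if config.variant == "resnet_unet":
                self.dec.append(_ResBlock(2 * cf[lvl], cf[lvl], (1, 1, 1), slope,
                                          rng=rng, dtype=dtype, name=f"dec{lvl}"))
            else:
                self.dec.append(_nn.Sequential([
                    _PlainBlock(2 * cf[lvl], cf[lvl], (1, 1, 1), slope, rng=rng,
                                dtype=dtype, name=f"dec{lvl}.0"),
                    _PlainBlock(cf[lvl], cf[lvl], (1, 1, 1), slope, rng=rng,
                                dtype=dtype, name=f"dec{lvl}.1"),
                ]))

        # deep-supervision heads at every decoder level except the coarsest
        self.head_levels = list(range(max(1, config.n_stages - 2)))
        self.heads = {lvl: _nn.Conv3d(cf[lvl], config.n_classes, ksize=(1, 1, 1),
                                      rng=rng, dtype=dtype, name=f"head{lvl}")
                      for lvl in self.head_levels}

        self._params = None
        self._skip_grads: dict[int, np.ndarray] = {}
        self._cat_channels = cf

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[_nn.Param]:
        if self._params is None:
            ps = []
            for stage in self.encoder:
                for b in stage:
                    ps += b.params()
            for lay in self.up:
                ps += lay.params()
            for lay in self.dec:
                ps += lay.params()
            for lvl in self.head_levels:
                ps += self.heads[lvl].params()
            self._params = ps
        return self._params

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    @property
    def n_classes(self) -> int:
        return self.config.n_classes

    def patch_divisor(self) -> tuple[int, int, int]:
        return self.config.patch_divisor()

    def _check_patch(self, shape) -> None:
        div = self.patch_divisor()
        if any(s % d for s, d in zip(shape, div)):
            raise ValueError(
                f"patch spatial shape {tuple(shape)} must be divisible by {div} "
                f"(cumulative downsampling stride)")

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> dict[int, np.ndarray]:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:
            x = x[..., None]
        self._check_patch(x.shape[1:4])
        skips = []
        h = x
        for stage in self.encoder:
            for b in stage:
                h = b.forward(h)
            skips.append(h)
        levels = self.head_levels if (train and self.config.deep_supervision) else [0]
        self._active_levels = levels
        outs = {}
        h = skips[-1]
        for lvl in reversed(range(self.config.n_stages - 1)):
            h = self.up[lvl].forward(h)
            h = np.concatenate([h, skips[lvl]], axis=-1)
            h = self.dec[lvl].forward(h)
            if lvl in levels:
                outs[lvl] = self.heads[lvl].forward(h)
        return outs

    def backward(self, dscores: dict[int, np.ndarray]) -> None:
        cfg = self.config
        skip_grads: dict[int, np.ndarray] = {}
        g = None
        for lvl in range(cfg.n_stages - 1):
            gh = self.heads[lvl].backward(dscores[lvl]) if lvl in dscores else None
            if g is None:
                g = gh
            elif gh is not None:
                g = g + gh
            g_cat = self.dec[lvl].backward(g)
            c = self._cat_channels[lvl]
            g_up, skip_grads[lvl] = g_cat[..., :c], g_cat[..., c:]
            g = self.up[lvl].backward(g_up)
        for i in reversed(range(cfg.n_stages)):
            if i < cfg.n_stages - 1:
                g = g + skip_grads[i]
            for b in reversed(self.encoder[i]):
                g = b.backward(g)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward: full-resolution per-class scores."""
        return self.forward(x, train=False)[0]

    # -- (de)serialisation --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i:04d}": p.value for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i:04d}"], dtype=self.dtype)
            if arr.shape != p.value.shape:
                raise ValueError(f"checkpoint/config mismatch at parameter {i}: "
                                 f"{arr.shape} vs {p.value.shape}")
            p.value[...] = arr


def build_network(cfg: NetworkConfig, seed: int = 0, dtype=np.float32) -> SegNetwork:
    """Instantiate a network; identical ``(cfg, seed)`` gives identical weights."""
    return SegNetwork(cfg, seed=seed, dtype=dtype)


def softmax_probabilities(scores: np.ndarray) -> np.ndarray:
    """Per-voxel class probabilities from raw scores (last axis = classes)."""
    scores = np.asarray(scores)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite network scores")
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
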