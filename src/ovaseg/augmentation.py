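"""On-the-fly training augmentation.

Spatial transforms (rotation, scaling, flipping) are applied identically
to the image and the label patch — labels by nearest-neighbour so the
label set never grows — and grey-value transforms (Gaussian noise,
multiplicative scaling, contrast, blurring, gamma) touch the image only.
Rotation and scaling are realised as one combined continuous resampling
to avoid double interpolation.

Magnitudes and probabilities follow the common convention of
self-configuring segmentation frameworks; all are configurable.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import ndimage

__all__ = ["AugmentConfig", "augment_pair"]


class AugmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    p_rotation: float = 0.2
    rotation_deg: tuple[float, float] = (-30.0, 30.0)  # in-plane (y, x)
    p_scaling: float = 0.2
    scaling: tuple[float, float] = (0.7, 1.4)
    p_flip: float = 0.5  # per axis

    p_noise: float = 0.2
    noise_sd: tuple[float, float] = (0.0, 0.1)
    p_multiplicative: float = 0.2
    multiplicative: tuple[float, float] = (0.7, 1.3)
    p_contrast: float = 0.2
    contrast: tuple[float, float] = (0.65, 1.5)
    p_blur: float = 0.2
    blur_sd: tuple[float, float] = (0.5, 1.5)
    p_gamma: float = 0.2
    gamma: tuple[float, float] = (0.7, 1.5)

    @model_validator(mode="after")
    def _valid(self):
        for f in ("p_rotation", "p_scaling", "p_flip", "p_noise", "p_multiplicative",
                  "p_contrast", "p_blur", "p_gamma"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        for f in ("rotation_deg", "scaling", "noise_sd", "multiplicative",
                  "contrast", "blur_sd", "gamma"):
            lo, hi = getattr(self, f)
            if lo > hi:
                raise ValueError(f"{f} range is empty: {(lo, hi)}")
        if self.gamma[0] <= 0:
            raise ValueError("gamma range must be positive")
        return self

    @classmethod
    def identity(cls) -> "AugmentConfig":
        """All application probabilities zero — the identity transform."""
        return cls(p_rotation=0, p_scaling=0, p_flip=0, p_noise=0,
                   p_multiplicative=0, p_contrast=0, p_blur=0, p_gamma=0)


def _apply_gamma(img: np.ndarray, g: float) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-8:
        # degenerate (constant) patch: apply the exponent to the raw value
        return np.power(np.clip(img, 0.0, None), g)
    return np.power((img - lo) / (hi - lo), g) * (hi - lo) + lo


def augment_pair(image: np.ndarray, labels: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Augment an aligned (image, labels) patch pair.

    A fixed random state yields an identical augmented pair; an
    all-probabilities-zero config is the identity.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError(f"misaligned patches: image {image.shape} vs labels {labels.shape}")

    # ---- combined rotation + scaling (one resampling) ----
    do_rot = rng.uniform() < cfg.p_rotation
    do_scale = rng.uniform() < cfg.p_scaling
    theta = np.deg2rad(rng.uniform(*cfg.rotation_deg)) if do_rot else 0.0
    scale = rng.uniform(*cfg.scaling) if do_scale else 1.0
    if do_rot or do_scale:
        c, s = np.cos(theta), np.sin(theta)
        # in-plane (y, x) rotation about the patch centre, isotropic scaling
        mat = np.array([[1.0, 0.0, 0.0],
                        [0.0, c, -s],
                        [0.0, s, c]]) / scale
        centre = (np.asarray(image.shape) - 1) / 2.0
        offset = centre - mat @ centre
        image = ndimage.affine_transform(image.astype(np.float32), mat, offset=offset,
                                         order=1, mode="nearest")
        labels = ndimage.affine_transform(labels, mat, offset=offset, order=0,
                                          mode="constant", cval=0)

    # ---- flips ----
    for ax in range(3):
        if rng.uniform() < cfg.p_flip:
            image = np.flip(image, axis=ax)
            labels = np.flip(labels, axis=ax)

    # ---- grey-value transforms (image only) ----
    image = np.ascontiguousarray(image, dtype=np.float32)
    if rng.uniform() < cfg.p_noise:
        sd = rng.uniform(*cfg.noise_sd)
        image = image + rng.normal(0.0, sd, size=image.shape).astype(np.float32)
    if rng.uniform() < cfg.p_multiplicative:
        image = image * rng.uniform(*cfg.multiplicative)
    if rng.uniform() < cfg.p_contrast:
        f = rng.uniform(*cfg.contrast)
        mu = image.mean()
        image = mu + (image - mu) * f
    if rng.uniform() < cfg.p_blur:
        image = ndimage.gaussian_filter(image, rng.uniform(*cfg.blur_sd))
    if rng.uniform() < cfg.p_gamma:
        image = _apply_gamma(image, rng.uniform(*cfg.gamma))

    return np.ascontiguousarray(image, dtype=np.float32), np.ascontiguousarray(labels)
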