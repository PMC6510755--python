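"""Training-set augmentation: rotation, scaling, translation, noise.

The training pool is expanded ``factor``-fold: each original image is kept
and ``factor - 1`` independently randomized variants are added.  Validation
and test images must never pass through this module; the orchestration layer
enforces that.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, EmptyInputError
from .projection import MIPImage

__all__ = ["AugmentConfig", "augment_set"]


@dataclass(frozen=True)
class AugmentConfig:
    factor: int = 5
    rotation_max: float = 10.0  # degrees, either direction
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_max: float = 4.0  # pixels, either axis
    noise_sd: float = 0.02  # gray units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ConfigurationError("augmentation factor must be >= 1")
        lo, hi = self.scale_range
        if not lo <= 1.0 <= hi:
            raise ConfigurationError("scale_range must contain 1.0 (identity)")
        if self.rotation_max < 0 or self.translate_max < 0 or self.noise_sd < 0:
            raise ConfigurationError("augmentation magnitudes must be nonnegative")


def _transform(pix: np.ndarray, rot: float, scale: float, tr: tuple[float, float]) -> np.ndarray:
    th = np.deg2rad(rot)
    c, s = np.cos(th), np.sin(th)
    # output->input map: rotate about centre, inverse-scale, then shift
    mat = np.array([[c, -s], [s, c]]) / scale
    centre = (np.asarray(pix.shape) - 1) / 2.0
    offset = centre - mat @ (centre + np.asarray(tr))
    return ndimage.affine_transform(pix, mat, offset=offset, order=1, mode="constant", cval=0.0)


def augment_set(images: list[MIPImage], cfg: AugmentConfig) -> list[MIPImage]:
    """Expand ``images`` to ``cfg.factor * len(images)`` images.

    Output order: for each input image, the untouched original followed by
    its variants.  Transform parameters are recorded in each variant's
    ``meta`` for provenance; the whole expansion is deterministic in
    ``cfg.seed``.
    """
    if not images:
        raise EmptyInputError("augment_set requires a nonempty image list")
    rng = np.random.default_rng(cfg.seed)
    out: list[MIPImage] = []
    for idx, im in enumerate(images):
        out.append(im)
        for k in range(cfg.factor - 1):
            rot = float(rng.uniform(-cfg.rotation_max, cfg.rotation_max))
            scale = float(rng.uniform(*cfg.scale_range))
            tr = (
                float(rng.uniform(-cfg.translate_max, cfg.translate_max)),
                float(rng.uniform(-cfg.translate_max, cfg.translate_max)),
            )
            pix = _transform(im.pixels.astype(np.float64), rot, scale, tr)
            if cfg.noise_sd > 0:
                pix = pix + rng.normal(0.0, cfg.noise_sd, size=pix.shape)
            pix = np.clip(pix, 0.0, 1.0).astype(np.float32)
            meta = {
                **im.meta,
                "source_id": f"{im.patient_id}:{idx}",
                "aug_rotation": rot,
                "aug_scale": scale,
                "aug_translate": list(tr),
                "aug_noise_sd": cfg.noise_sd,
            }
            out.append(replace(im, pixels=pix, meta=meta))
    return out
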