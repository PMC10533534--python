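"""Stochastic image augmentation used for training and for test-time
augmentation: horizontal flip, rotation, zoom, additive Gaussian noise,
brightness shift and contrast scaling.

Brightness limits are given on the conventional 0..255 intensity scale
and rescaled internally, since the pipeline holds pixels in [0, 1].
The geometric part is a single batched inverse-mapped bilinear warp, so
augmenting a training batch costs a few vectorized numpy operations
rather than one interpolation call per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentConfig", "augment_image", "augment_batch"]


@dataclass
class AugmentConfig:
    horizontal_flip: bool = True
    rotation_deg: tuple[float, float] = (-20.0, 20.0)
    zoom: tuple[float, float] = (0.80, 1.05)
    noise_sigma: tuple[float, float] = (0.0, 0.08)
    brightness_255: tuple[float, float] = (-10.0, 10.0)
    contrast: tuple[float, float] = (0.7, 1.3)

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(horizontal_flip=False, rotation_deg=(0, 0), zoom=(1, 1),
                   noise_sigma=(0, 0), brightness_255=(0, 0), contrast=(1, 1))


def _warp(imgs: np.ndarray, angles_deg: np.ndarray,
          zooms: np.ndarray) -> np.ndarray:
    """Rotate+zoom every image about its center (inverse-mapped bilinear
    interpolation, edge-clamped)."""
    b, s, _ = imgs.shape
    th = np.deg2rad(angles_deg)
    c, sn = np.cos(th) / zooms, np.sin(th) / zooms  # inverse map: out -> in
    ctr = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    dy, dx = yy - ctr, xx - ctr
    src_y = ctr + c[:, None, None] * dy - sn[:, None, None] * dx
    src_x = ctr + sn[:, None, None] * dy + c[:, None, None] * dx
    y0 = np.clip(np.floor(src_y).astype(np.intp), 0, s - 2)
    x0 = np.clip(np.floor(src_x).astype(np.intp), 0, s - 2)
    wy = np.clip(src_y - y0, 0.0, 1.0)
    wx = np.clip(src_x - x0, 0.0, 1.0)
    flat = imgs.reshape(-1)
    base = (np.arange(b) * s * s)[:, None, None]
    idx = base + y0 * s + x0
    v00 = flat[idx]
    v01 = flat[idx + 1]
    v10 = flat[idx + s]
    v11 = flat[idx + s + 1]
    top = v00 * (1 - wx) + v01 * wx
    bot = v10 * (1 - wx) + v11 * wx
    return top * (1 - wy) + bot * wy


def augment_batch(imgs: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """One random augmentation draw per image. The draw order is fixed,
    so results are reproducible for a given rng state."""
    b = len(imgs)
    out = imgs.copy()
    if cfg.horizontal_flip:
        flip = rng.random(b) < 0.5
        out[flip] = out[flip, :, ::-1]
    angles = rng.uniform(*cfg.rotation_deg, size=b)
    zooms = rng.uniform(*cfg.zoom, size=b)
    if np.any(np.abs(angles) > 1e-9) or np.any(np.abs(zooms - 1) > 1e-9):
        out = _warp(out, angles, zooms)
    sig = rng.uniform(*cfg.noise_sigma, size=b)
    if np.any(sig > 0):
        out = out + rng.standard_normal(out.shape) * sig[:, None, None]
    shift = rng.uniform(*cfg.brightness_255, size=b) / 255.0
    gain = rng.uniform(*cfg.contrast, size=b)
    m = out.mean(axis=(1, 2))
    out = ((out - m[:, None, None]) * gain[:, None, None]
           + m[:, None, None] + shift[:, None, None])
    return np.clip(out, 0.0, 1.0)


def augment_image(img: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    return augment_batch(img[None], cfg, rng)[0]
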