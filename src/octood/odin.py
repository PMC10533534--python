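"""ODIN: temperature scaling plus a signed input perturbation.

The detector perturbs a test image against the gradient of the
temperature-scaled log softmax of the predicted class,

    x~ = x − eps * sign( −∇_x log S_yhat(x; T) ),

which preferentially boosts the top-class confidence of in-distribution
inputs, and then scores the sample as 1 − max_i S_i(x~; T). With T = 1
and eps = 0 this reduces exactly to the maximum-probability baseline.
T and eps are picked by exhaustive grid search maximizing the OOD AUC on
a validation set of inliers plus held-out (pool) outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evalstats import auc
from .nets import CompactNet, softmax

__all__ = ["OdinConfig", "odin_perturb", "odin_score", "odin_grid_search"]


def _default_epsilons() -> tuple[float, ...]:
    eps = np.concatenate([np.linspace(0.0, 0.04, 21), np.linspace(0.04, 0.1, 10)])
    return tuple(np.unique(np.round(eps, 10)))


@dataclass
class OdinConfig:
    temperatures: tuple[float, ...] = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)
    epsilons: tuple[float, ...] = field(default_factory=_default_epsilons)
    # retained for completeness; unused because evaluation is
    # threshold-free (AUC)
    delta: float | None = None


def _top_class_grad(model: CompactNet, images: np.ndarray, T: float):
    """Input gradient of log S_yhat(x; T) for a batch, plus the cache."""
    cache = model.forward(images)
    logits = cache["logits"]
    yhat = logits.argmax(axis=1)
    pT = softmax(logits / T)
    d = -pT
    d[np.arange(len(d)), yhat] += 1.0
    d /= T  # d log softmax_yhat(f/T) / d f
    return model.input_gradient(cache, d), cache


def odin_perturb(model: CompactNet, images: np.ndarray, T: float,
                 eps: float) -> np.ndarray:
    """Apply the signed-gradient perturbation; eps = 0 returns the input."""
    if eps < 0:
        raise ValueError("perturbation magnitude eps must be >= 0")
    if eps == 0:
        return images
    g, _ = _top_class_grad(model, images, T)
    return images + eps * np.sign(g)


def odin_score(model: CompactNet, images: np.ndarray, T: float = 1.0,
               eps: float = 0.0) -> np.ndarray:
    """1 − max_i S_i(x~; T) per image (higher = more OOD)."""
    single = images.ndim == 2
    x = images[None] if single else images
    xt = odin_perturb(model, x, T, eps)
    p = softmax(model.logits(xt) / T)
    s = 1.0 - p.max(axis=1)
    return float(s[0]) if single else s


def odin_grid_search(model: CompactNet, val_inliers: np.ndarray,
                     val_outliers: np.ndarray,
                     config: OdinConfig | None = None,
                     return_surface: bool = False):
    """Exhaustive (T, eps) grid search maximizing the validation OOD AUC.

    Ties are broken toward smaller eps, then smaller T. For a fixed T
    the perturbation sign is constant in eps, so the gradient is
    computed once per temperature. Optionally returns the full AUC
    surface as a {(T, eps): auc} dict.
    """
    cfg = config or OdinConfig()
    surface: dict[tuple[float, float], float] = {}
    best = None
    for T in cfg.temperatures:
        sg_in = np.sign(_top_class_grad(model, val_inliers, T)[0])
        sg_out = np.sign(_top_class_grad(model, val_outliers, T)[0])
        for eps in cfg.epsilons:
            p_in = softmax(model.logits(val_inliers + eps * sg_in) / T)
            p_out = softmax(model.logits(val_outliers + eps * sg_out) / T)
            a = auc(1.0 - p_in.max(axis=1), 1.0 - p_out.max(axis=1))
            surface[(T, eps)] = a
            key = (a, -eps, -T)
            if best is None or key > best[0]:
                best = (key, (T, eps))
    (T_star, eps_star) = best[1]
    if return_surface:
        return T_star, eps_star, surface
    return T_star, eps_star
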