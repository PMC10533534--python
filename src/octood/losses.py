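"""Training losses: cross-entropy, entropy-regularized outlier exposure,
and the evidential Dirichlet loss.

Each loss comes in two flavours: a scalar *value* function operating on
probabilities / Dirichlet parameters (the contract the rest of the
package and the tests consume), and a ``*_grad`` companion returning the
gradient w.r.t. the raw head outputs, used by the training loop.

The evidential loss is the expected-squared-error Bayes risk of the
Dirichlet plus an annealed KL regularizer that pulls *misleading*
evidence (evidence on wrong classes) toward the uniform Dirichlet:

    L(alpha, y) = sum_k [ (y_k - p_k)^2 + p_k (1 - p_k) / (S + 1) ]
                  + lambda_t * KL( Dir(alpha_tilde) || Dir(1) )

with ``p = alpha / S``, ``S = sum(alpha)`` and
``alpha_tilde = y + (1 - y) * alpha`` (the correct class's alpha reset
to 1 so correct evidence is never penalized). ``lambda_t`` is the
annealing coefficient, ramped from 0 to 1 over the first training epochs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, psi, polygamma

from .nets import DirichletOutput, softmax, softplus

__all__ = ["loss_ce", "loss_oe_entropy", "loss_dirichlet",
           "kl_dirichlet_uniform", "ce_grad_logits", "uniform_ce_grad_logits",
           "dirichlet_grad_logits", "dirichlet_uniform_ce_grad_logits"]

_EPS = 1e-12


def _as_batch(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p[None] if p.ndim == 1 else p


def loss_ce(p: np.ndarray, label: int | np.ndarray) -> float:
    """Mean categorical cross-entropy of probability vector(s) ``p``
    against integer label(s)."""
    p = _as_batch(p)
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    picked = p[np.arange(len(p)), labels]
    return float(np.mean(-np.log(np.clip(picked, _EPS, None))))


def loss_oe_entropy(inlier_p: np.ndarray, inlier_labels: np.ndarray,
                    outlier_p: np.ndarray | None, lam: float = 0.5) -> float:
    """Cross-entropy on inliers plus ``lam`` times the mean cross-entropy
    between the uniform target and the outlier predictions.

    The regularizer ``-(1/K) sum_k log p_k`` is minimized (value
    ``ln K``) exactly when the outlier prediction is uniform; its
    gradient pushes outlier predictions toward the uniform distribution.
    An empty/None outlier batch reduces to the plain inlier term.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    total = loss_ce(inlier_p, inlier_labels)
    if outlier_p is None or np.size(outlier_p) == 0:
        return total
    q = _as_batch(outlier_p)
    reg = float(np.mean(-np.mean(np.log(np.clip(q, _EPS, None)), axis=1)))
    return total + lam * reg


def kl_dirichlet_uniform(alpha: np.ndarray) -> np.ndarray:
    """KL( Dir(alpha) || Dir(1,...,1) ), elementwise over the batch."""
    alpha = _as_batch(alpha)
    K = alpha.shape[-1]
    S = alpha.sum(axis=-1)
    return (gammaln(S) - gammaln(alpha).sum(axis=-1) - gammaln(K)
            + ((alpha - 1.0) * (psi(alpha) - psi(S)[..., None])).sum(axis=-1))


def _dirichlet_terms(alpha: np.ndarray, y: np.ndarray):
    S = alpha.sum(axis=-1, keepdims=True)
    p = alpha / S
    risk = ((y - p) ** 2 + p * (1.0 - p) / (S + 1.0)).sum(axis=-1)
    return S[..., 0], p, risk


def loss_dirichlet(output: "DirichletOutput | np.ndarray",
                   label: int | np.ndarray, annealing: float = 1.0) -> float:
    """Evidential loss (mean over the batch); see module docstring.

    ``output`` is a :class:`DirichletOutput` or an alpha array
    (``alpha_k >= 1``). ``annealing`` scales the KL term.
    """
    alpha = output.alpha if isinstance(output, DirichletOutput) else np.asarray(output, float)
    alpha = _as_batch(alpha)
    if np.any(alpha < 1.0 - 1e-9):
        raise ValueError("alpha entries must be >= 1 (evidence >= 0)")
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    y = np.zeros_like(alpha)
    y[np.arange(len(alpha)), labels] = 1.0
    _, _, risk = _dirichlet_terms(alpha, y)
    alpha_tilde = y + (1.0 - y) * alpha
    kl = kl_dirichlet_uniform(alpha_tilde)
    return float(np.mean(risk + annealing * kl))


# ----------------------------------------------------------------------
# gradients w.r.t. raw head outputs (used by the training loop)
# ----------------------------------------------------------------------


def ce_grad_logits(logits: np.ndarray, labels: np.ndarray, scale: float = 1.0):
    """(loss, dlogits) for softmax cross-entropy; dlogits includes the
    1/batch factor times ``scale``."""
    p = softmax(logits)
    n = len(logits)
    y = np.zeros_like(p)
    y[np.arange(n), labels] = 1.0
    loss = loss_ce(p, labels)
    return loss, scale * (p - y) / n


def uniform_ce_grad_logits(logits: np.ndarray, scale: float = 1.0):
    """(value, dlogits) of the mean uniform-target cross-entropy of
    softmax(logits) — the outlier-exposure regularizer."""
    p = softmax(logits)
    n, K = p.shape
    u = np.full_like(p, 1.0 / K)
    val = float(np.mean(-np.mean(np.log(np.clip(p, _EPS, None)), axis=1)))
    return val, scale * (p - u) / n


def dirichlet_grad_logits(logits: np.ndarray, labels: np.ndarray,
                          annealing: float, scale: float = 1.0):
    """(loss, dlogits) of the evidential loss for a dirichlet head whose
    evidence is ``softplus(logits)``. Gradients are analytic; they are
    finite-difference-checked in the test suite."""
    ev = softplus(logits)
    alpha = ev + 1.0
    n, K = alpha.shape
    y = np.zeros_like(alpha)
    y[np.arange(n), labels] = 1.0
    S, p, risk = _dirichlet_terms(alpha, y)
    Q = np.sum(p * p, axis=-1)

    # d(risk)/d(alpha_j), rows = samples
    dA = (2.0 / S[:, None]) * ((p - y) - np.sum((p - y) * p, axis=-1, keepdims=True))
    dB = (-2.0 * (p - Q[:, None]) / (S * (S + 1.0))[:, None]
          - ((1.0 - Q) / (S + 1.0) ** 2)[:, None])
    drisk = dA + dB

    # KL(Dir(alpha_tilde) || Dir(1)) and its gradient
    at = y + (1.0 - y) * alpha
    St = at.sum(axis=-1)
    kl = kl_dirichlet_uniform(at)
    dkl_dat = (at - 1.0) * polygamma(1, at) - ((St - K) * polygamma(1, St))[:, None]
    dkl = (1.0 - y) * dkl_dat

    dalpha = drisk + annealing * dkl
    dlogits = dalpha * _sigmoid(logits)  # d softplus / d z
    loss = float(np.mean(risk + annealing * kl))
    return loss, scale * dlogits / n


def dirichlet_uniform_ce_grad_logits(logits: np.ndarray, scale: float = 1.0):
    """(value, dlogits) of the uniform-target cross-entropy of the
    Dirichlet mean ``p = alpha/S`` — the outlier-exposure regularizer for
    evidential heads."""
    ev = softplus(logits)
    alpha = ev + 1.0
    n, K = alpha.shape
    S = alpha.sum(axis=-1, keepdims=True)
    p = alpha / S
    val = float(np.mean(-np.mean(np.log(np.clip(p, _EPS, None)), axis=1)))
    # d/d alpha_j of -(1/K) sum_k log(alpha_k / S) = -(1/K)(1/alpha_j) + 1/S
    dalpha = -(1.0 / K) / alpha + 1.0 / S
    dlogits = dalpha * _sigmoid(logits)
    return val, scale * dlogits / n


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
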