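"""Out-of-distribution scoring metrics.

Every metric returns a scalar (or an array, one scalar per sample)
oriented so that **higher means more out-of-distribution**:

* ``score_mp``          — 1 − max class probability;
* ``score_entropy``     — Shannon entropy of the class probabilities;
* ``score_dirichlet_u`` — Dirichlet uncertainty u = K / S;
* ``score_cosine``      — 1 − max cosine similarity to inlier class
  centers in the penultimate feature space;
* ``score_mahalanobis`` — minimum Mahalanobis distance to the
  class-conditional Gaussians (tied, shrunk covariance);
* ``score_us`` / ``score_uh`` — across-inference spread of a prediction
  stack (mean class variance / mean base-N class entropy);
* ``score_rbp``         — the probability mass on the abstention class.

Feature-space models are fitted on *training inlier* features only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import EmpiricalCovariance, ShrunkCovariance

from .nets import DirichletOutput, softmax

__all__ = ["PredictionStack", "ClassCenters", "GaussianFeatureModel",
           "score_mp", "score_entropy", "score_dirichlet_u",
           "fit_centers", "score_cosine",
           "fit_gaussians", "score_mahalanobis",
           "score_us", "score_uh", "score_rbp",
           "temperature_softmax", "aggregate_stack"]

_EPS = 1e-12


def _rows(p: np.ndarray) -> tuple[np.ndarray, bool]:
    p = np.asarray(p, dtype=float)
    return (p[None], True) if p.ndim == 1 else (p, False)


def _unwrap(v: np.ndarray, single: bool):
    return float(v[0]) if single else v


# ----------------------------------------------------------------------
# probability-space metrics
# ----------------------------------------------------------------------


def score_mp(p: np.ndarray):
    """1 − max_k p_k (maximum-probability score, flipped to higher-is-OOD)."""
    p, single = _rows(p)
    return _unwrap(1.0 - p.max(axis=-1), single)


def score_entropy(p: np.ndarray):
    """Shannon entropy −Σ p ln p with the convention 0·ln 0 = 0."""
    p, single = _rows(p)
    terms = np.where(p > 0, p * np.log(np.clip(p, _EPS, None)), 0.0)
    return _unwrap(-terms.sum(axis=-1), single)


def score_dirichlet_u(output: DirichletOutput | np.ndarray):
    """Dirichlet uncertainty u = K / Σ_k (e_k + 1); equals 1 at zero
    evidence."""
    ev = output.evidence if isinstance(output, DirichletOutput) else np.asarray(output, float)
    ev, single = _rows(ev)
    K = ev.shape[-1]
    return _unwrap(K / (ev + 1.0).sum(axis=-1), single)


def score_rbp(p: np.ndarray):
    """Probability of the abstention (reject-bucket) class, i.e. the last
    entry of a (K+1)-length probability vector."""
    p, single = _rows(p)
    return _unwrap(p[:, -1].copy(), single)


def temperature_softmax(logits: np.ndarray, T: float) -> np.ndarray:
    """Softmax of logits / T. Argmax-preserving for every T > 0."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return softmax(np.asarray(logits, float) / T)


# ----------------------------------------------------------------------
# feature-space metrics
# ----------------------------------------------------------------------


@dataclass
class ClassCenters:
    classes: tuple[str, ...]
    centers: np.ndarray  # (C, D)


def fit_centers(features: np.ndarray, labels: np.ndarray) -> ClassCenters:
    """Mean feature vector per inlier class (fitted on training inliers)."""
    classes = tuple(sorted(set(labels)))
    centers = np.stack([features[labels == c].mean(axis=0) for c in classes])
    norms = np.linalg.norm(centers, axis=1)
    if np.any(norms < _EPS):
        raise ValueError("a class center has zero norm; cannot use cosine scoring")
    return ClassCenters(classes=classes, centers=centers)


def score_cosine(x: np.ndarray, centers: ClassCenters):
    """1 − max over inlier classes of cos(x, center)."""
    x, single = _rows(x)
    nx = np.linalg.norm(x, axis=1)
    if np.any(nx < _EPS):
        raise ValueError("zero-norm feature vector; cosine score undefined")
    C = centers.centers
    cn = np.linalg.norm(C, axis=1)
    sims = (x @ C.T) / (nx[:, None] * cn[None, :])
    return _unwrap(1.0 - sims.max(axis=1), single)


@dataclass
class GaussianFeatureModel:
    """Class-conditional Gaussians with a tied (shared) covariance.

    The covariance is pooled over classes after centering each class at
    its own mean, then shrunk toward the scaled identity:
    ``C_shrunk = (1 − s)·C + s·(tr C / D)·I``, which keeps it positive
    definite even when samples are scarce relative to the feature
    dimension.
    """

    classes: tuple[str, ...]
    means: np.ndarray       # (C, D)
    covariance: np.ndarray  # (D, D)
    precision: np.ndarray   # (D, D)
    shrinkage: float


def fit_gaussians(features: np.ndarray, labels: np.ndarray,
                  shrinkage: float = 0.1) -> GaussianFeatureModel:
    classes = tuple(sorted(set(labels)))
    means = np.stack([features[labels == c].mean(axis=0) for c in classes])
    centered = np.concatenate([features[labels == c] - m
                               for c, m in zip(classes, means)])
    if shrinkage > 0:
        est = ShrunkCovariance(shrinkage=shrinkage, assume_centered=True)
    else:
        est = EmpiricalCovariance(assume_centered=True)
    est.fit(centered)
    cov = est.covariance_
    eigmin = float(np.linalg.eigvalsh(cov)[0])
    if eigmin <= 1e-10:
        raise ValueError(
            "covariance is singular; refit with a positive shrinkage "
            "coefficient (e.g. fit_gaussians(..., shrinkage=0.1))")
    precision = np.linalg.inv(cov)
    return GaussianFeatureModel(classes=classes, means=means, covariance=cov,
                                precision=precision, shrinkage=shrinkage)


def score_mahalanobis(x: np.ndarray, model: GaussianFeatureModel):
    """min over classes of sqrt((x − m_c)^T C^{-1} (x − m_c))."""
    x, single = _rows(x)
    d2 = np.empty((len(x), len(model.classes)))
    for j, m in enumerate(model.means):
        diff = x - m
        d2[:, j] = np.einsum("ij,jk,ik->i", diff, model.precision, diff)
    return _unwrap(np.sqrt(np.clip(d2, 0, None)).min(axis=1), single)


# ----------------------------------------------------------------------
# prediction-stack metrics (dropout / ensemble / test-time augmentation)
# ----------------------------------------------------------------------


@dataclass
class PredictionStack:
    """N repeated probability vectors for one sample."""

    probs: np.ndarray  # (N, K)
    source: str = "ensemble"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("stack must be a (N, K) matrix")
        if np.any(self.probs < -1e-9):
            raise ValueError("stack entries must be non-negative")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each stack row must sum to 1 (tolerance 1e-6)")


def score_us(stack: PredictionStack) -> float:
    """Mean over classes of the across-inference (population) variance of
    that class's probability."""
    p = stack.probs
    if len(p) < 2:
        raise ValueError("variance-based metrics need N >= 2 inferences")
    return float(p.var(axis=0, ddof=0).mean())


def score_uh(stack: PredictionStack) -> float:
    """Mean over classes of the base-N entropy of the raw across-inference
    probability sequence: U_H = (1/K) Σ_c [ −Σ_i y_ci log_N y_ci ].

    With confident, agreeing one-hot predictions every term vanishes
    (U_H = 0); spread-out probabilities across inferences raise it.
    """
    p = stack.probs
    N = len(p)
    if N < 2:
        raise ValueError("entropy-based stack metrics need N >= 2 inferences")
    terms = np.where(p > 0, -p * np.log(np.clip(p, _EPS, None)) / np.log(N), 0.0)
    return float(terms.sum(axis=0).mean())


def aggregate_stack(stack: PredictionStack) -> np.ndarray:
    """Arithmetic mean across inferences, renormalized to sum 1; lets the
    single-vector metrics (MP, entropy) apply to stack methods."""
    m = stack.probs.mean(axis=0)
    return m / m.sum()
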