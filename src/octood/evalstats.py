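"""Threshold-free evaluation statistics.

AUC here is always the Mann–Whitney probability that a randomly chosen
outlier outscores a randomly chosen inlier (ties counted 1/2), i.e. the
ROC AUC with outliers as the positive class. The class-balanced
bootstrap removes outlier class-imbalance bias: each of ``n_boot``
resamples draws, per outlier class, a without-replacement subset of the
size of the rarest class, pools them, and the per-resample AUCs are
averaged.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = ["auc", "balanced_bootstrap_auc", "macro_auc",
           "wilcoxon_compare", "cluster_cosine_distances"]


def auc(inlier_scores: np.ndarray, outlier_scores: np.ndarray) -> float:
    """ROC AUC of separating outliers (positives) from inliers by score."""
    a = np.asarray(inlier_scores, float)
    b = np.asarray(outlier_scores, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    return float(roc_auc_score(y, np.concatenate([a, b])))


def balanced_bootstrap_auc(inlier_scores: np.ndarray,
                           outlier_scores_by_class: Mapping[str, np.ndarray],
                           n_boot: int = 100, seed: int = 0):
    """Class-balanced bootstrap AUC; returns (mean, sd) over resamples.

    The spread is the standard deviation of the ``n_boot`` resample
    AUCs. With a single outlier class every resample is the full class,
    so the mean equals the plain AUC and the spread is 0.
    """
    if not outlier_scores_by_class:
        raise ValueError("at least one outlier class is required")
    arrays = {k: np.asarray(v, float) for k, v in outlier_scores_by_class.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"outlier class {k!r} has no scores")
    m = min(v.size for v in arrays.values())
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        pooled = np.concatenate([
            v if v.size == m else rng.choice(v, size=m, replace=False)
            for v in arrays.values()])
        vals[i] = auc(inlier_scores, pooled)
    return float(vals.mean()), float(vals.std(ddof=0))


def macro_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean of one-vs-rest AUCs over the K classes.

    ``labels`` are integer class indices into the columns of ``probs``;
    every class must be present.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    K = probs.shape[1]
    present = set(labels.tolist())
    if present != set(range(K)):
        missing = sorted(set(range(K)) - present)
        raise ValueError(f"labels missing classes {missing}; macro AUC undefined")
    per_class = [roc_auc_score((labels == k).astype(int), probs[:, k])
                 for k in range(K)]
    return float(np.mean(per_class))


def wilcoxon_compare(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value comparing two AUC samples.

    Exact enumeration when the combined sample is small (n <= 20) and
    tie-free; normal approximation otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def cluster_cosine_distances(features: np.ndarray, labels: np.ndarray,
                             inlier_classes=None) -> dict[str, float]:
    """Cosine distance from each outlier-class cluster center to the
    center of the pooled inlier cluster: 1 − cos(center_c, center_in).
    """
    from .synthgen import INLIER_CLASSES  # default taxonomy
    inlier_classes = tuple(inlier_classes or INLIER_CLASSES)
    labels = np.asarray(labels)
    in_mask = np.isin(labels, inlier_classes)
    if not in_mask.any():
        raise ValueError("no inlier samples present")
    c_in = features[in_mask].mean(axis=0)
    n_in = np.linalg.norm(c_in)
    out = {}
    for cls in sorted(set(labels[~in_mask].tolist())):
        c = features[labels == cls].mean(axis=0)
        out[cls] = float(1.0 - (c @ c_in) / (np.linalg.norm(c) * n_in))
    return out
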