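"""Benchmark orchestration: the method × metric matrix, the full
near/far OOD evaluation, and the few-shot outlier-exposure sweep.

Methods are training/inference strategies (plain softmax, evidential
Dirichlet head, MC dropout, a model ensemble, test-time augmentation,
temperature scaling, ODIN, and the two outlier-exposure variants);
metrics turn one model's outputs on a test image into a scalar OOD
score. Only the admissible pairs listed in ``ADMISSIBLE`` are ever
evaluated — e.g. the reject-bucket probability exists only for the
reject-bucket model, and the across-inference spread metrics only for
methods that produce a stack of predictions.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from .evalstats import auc, balanced_bootstrap_auc, cluster_cosine_distances, macro_auc
from .nets import CompactNet, build_model, extract_features, softmax
from .odin import OdinConfig, odin_grid_search, odin_perturb
from .scoring import (PredictionStack, aggregate_stack, fit_centers,
                      fit_gaussians, score_cosine, score_dirichlet_u,
                      score_entropy, score_mahalanobis, score_mp, score_rbp,
                      score_uh, score_us, temperature_softmax)
from .synthgen import INLIER_CLASSES, NEAR_OOD_CLASSES, SplitDataset
from .train import ExposureConfig, TrainConfig, train

__all__ = ["METHODS", "METRICS", "ADMISSIBLE", "run_benchmark",
           "run_fewshot_sweep", "score_test_set", "derive_seed"]

METRICS = ("mp", "entropy", "dirichlet_u", "rbp", "u_h", "u_s",
           "mahalanobis", "cosine")

ADMISSIBLE: dict[str, tuple[str, ...]] = {
    "softmax":          ("mp", "entropy", "mahalanobis", "cosine"),
    "dirichlet":        ("mp", "entropy", "dirichlet_u", "mahalanobis", "cosine"),
    "mc_dropout":       ("mp", "entropy", "u_h", "u_s"),
    "ensemble":         ("mp", "entropy", "u_h", "u_s"),
    "tta":              ("mp", "entropy", "u_h", "u_s"),
    "temp_scaling":     ("mp", "entropy", "mahalanobis", "cosine"),
    "odin":             ("mp", "entropy", "mahalanobis", "cosine"),
    "dirichlet_oe_ent": ("mp", "entropy", "dirichlet_u", "mahalanobis", "cosine"),
    "softmax_oe_ent":   ("mp", "entropy", "mahalanobis", "cosine"),
    "softmax_oe_rb":    ("mp", "entropy", "rbp", "mahalanobis", "cosine"),
}
METHODS = tuple(ADMISSIBLE)

_OE_METHODS = {"dirichlet_oe_ent", "softmax_oe_ent", "softmax_oe_rb"}
_HEAD_OF = {"dirichlet": "dirichlet", "dirichlet_oe_ent": "dirichlet",
            "softmax_oe_rb": "reject_bucket"}


def derive_seed(master: int, *keys) -> int:
    """Deterministic sub-seed from a master seed and string/int keys."""
    parts = [int(master)]
    for k in keys:
        parts.append(zlib.crc32(str(k).encode()) % 2**31)
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % 2**31)


# ----------------------------------------------------------------------
# per-model scoring machinery
# ----------------------------------------------------------------------


def _test_parts(dataset: SplitDataset):
    test_in = dataset.test.by_role("inlier")
    near = {c: dataset.test.by_label(c) for c in NEAR_OOD_CLASSES
            if len(dataset.test.by_label(c))}
    far = dataset.test.by_role("farOOD")
    return test_in, near, far


def _class_indices(labels: np.ndarray) -> np.ndarray:
    lut = {c: i for i, c in enumerate(INLIER_CLASSES)}
    return np.array([lut[c] for c in labels])


class _ModelScorer:
    """Produces per-sample OOD scores on arbitrary image batches for
    every metric admissible for one (method, trained model) pair."""

    def __init__(self, method: str, model: CompactNet, dataset: SplitDataset,
                 shrinkage: float, seed: int, n_repeats: int = 20,
                 ensemble: list[CompactNet] | None = None,
                 T: float = 1.0, eps: float = 0.0):
        self.method = method
        self.model = model
        self.ensemble = ensemble
        self.T = T
        self.eps = eps
        self.n_repeats = n_repeats
        self.seed = seed
        self._needs_features = any(
            m in ("mahalanobis", "cosine") for m in ADMISSIBLE[method])
        if self._needs_features:
            tr_in = dataset.train.by_role("inlier")
            feats = extract_features(model, tr_in.pixels)
            self.centers = fit_centers(feats, tr_in.labels)
            self.gauss = fit_gaussians(feats, tr_in.labels, shrinkage=shrinkage)

    # -- shared intermediate representations ---------------------------

    def _probs(self, X: np.ndarray) -> np.ndarray:
        if self.method == "temp_scaling":
            return temperature_softmax(self.model.logits(X), self.T)
        if self.method == "odin":
            xt = odin_perturb(self.model, X, self.T, self.eps)
            return temperature_softmax(self.model.logits(xt), self.T)
        return self.model.predict_proba(X)

    def _features(self, X: np.ndarray) -> np.ndarray:
        if self.method == "odin" and self.eps > 0:
            X = odin_perturb(self.model, X, self.T, self.eps)
        return extract_features(self.model, X)

    def _stacks(self, X: np.ndarray) -> np.ndarray:
        """(n_images, N, K) repeated probabilities."""
        if self.method == "ensemble":
            return np.stack([m.predict_proba(X) for m in self.ensemble], axis=1)
        if self.method == "mc_dropout":
            rng = np.random.default_rng(self.seed)
            return np.stack([self.model.predict_proba(X, training=True, rng=rng)
                             for _ in range(self.n_repeats)], axis=1)
        if self.method == "tta":
            from .augment import AugmentConfig, augment_batch
            rng = np.random.default_rng(self.seed)
            acfg = AugmentConfig()
            reps = [self.model.predict_proba(augment_batch(X, acfg, rng))
                    for _ in range(self.n_repeats)]
            return np.stack(reps, axis=1)
        raise ValueError(f"{self.method} does not produce prediction stacks")

    # -- public scoring -------------------------------------------------

    def scores(self, metric: str, X: np.ndarray) -> np.ndarray:
        if metric not in ADMISSIBLE[self.method]:
            raise ValueError(
                f"metric {metric!r} is not admissible for method "
                f"{self.method!r}; see octood.benchmark.ADMISSIBLE")
        stackful = self.method in ("mc_dropout", "ensemble", "tta")
        if metric in ("mp", "entropy") and stackful:
            stacks = self._stacks(X)
            agg = np.stack([aggregate_stack(PredictionStack(s)) for s in stacks])
            return score_mp(agg) if metric == "mp" else score_entropy(agg)
        if metric in ("u_s", "u_h"):
            stacks = self._stacks(X)
            fn = score_us if metric == "u_s" else score_uh
            return np.array([fn(PredictionStack(s)) for s in stacks])
        if metric == "mp":
            return score_mp(self._probs(X))
        if metric == "entropy":
            return score_entropy(self._probs(X))
        if metric == "rbp":
            return score_rbp(self._probs(X))
        if metric == "dirichlet_u":
            return score_dirichlet_u(self.model.dirichlet_output(X))
        if metric == "cosine":
            return score_cosine(self._features(X), self.centers)
        if metric == "mahalanobis":
            return score_mahalanobis(self._features(X), self.gauss)
        raise ValueError(f"unknown metric {metric!r}")

    def classification_probs(self, X: np.ndarray) -> np.ndarray:
        """K-class probabilities for inlier classification AUC (the
        reject-bucket head drops its abstention column)."""
        p = self.model.predict_proba(X)
        return p[:, :len(INLIER_CLASSES)]


def _evaluate(scorer: _ModelScorer, dataset: SplitDataset, metrics,
              n_boot: int, boot_seed: int, base_row: dict) -> list[dict]:
    test_in, near, far = _test_parts(dataset)
    probs_in = scorer.classification_probs(test_in.pixels)
    macro = macro_auc(probs_in, _class_indices(test_in.labels))
    rows = []
    for metric in metrics:
        s_in = scorer.scores(metric, test_in.pixels)
        per_class = {c: scorer.scores(metric, s.pixels) for c, s in near.items()}
        row = dict(base_row, metric=metric, macro_auc=macro)
        for c, s in per_class.items():
            row[f"auc_{c}"] = auc(s_in, s)
        if per_class:
            mean, sd = balanced_bootstrap_auc(s_in, per_class, n_boot=n_boot,
                                              seed=boot_seed)
            row["near_auc"] = mean
            row["near_sd"] = sd
        if len(far):
            row["far_auc"] = auc(s_in, scorer.scores(metric, far.pixels))
        rows.append(row)
    return rows


# ----------------------------------------------------------------------
# model training per method (with sharing of the softmax backbone)
# ----------------------------------------------------------------------


def _fit(dataset: SplitDataset, head: str, tcfg: TrainConfig, seed: int,
         exposure: ExposureConfig | None = None) -> CompactNet:
    cfg = dataset.config
    model = build_model(head, K=len(INLIER_CLASSES), side=cfg.side,
                        seed=derive_seed(seed, "init"))
    tc = replace(tcfg, seed=derive_seed(seed, "train"))
    train(model, dataset.train, dataset.val, tc,
          exposure=exposure, pool=dataset.pool)
    return model


def _validation_ood(dataset: SplitDataset, seed: int, per_class: int = 34):
    """Near-OOD images for ODIN/temperature tuning, drawn from the
    exposure pool (never from the test set)."""
    rng = np.random.default_rng(seed)
    parts = []
    for c in NEAR_OOD_CLASSES:
        s = dataset.pool.by_label(c)
        if len(s) == 0:
            continue
        idx = rng.choice(len(s), size=min(per_class, len(s)), replace=False)
        parts.append(s.pixels[idx])
    if not parts:
        raise ValueError("exposure pool holds no near-OOD images for tuning")
    return np.concatenate(parts)


def run_benchmark(dataset: SplitDataset, methods=None, metrics=None,
                  train_config: TrainConfig | None = None,
                  exposure_n: int = 4, n_repeats: int = 20,
                  ensemble_size: int = 20, shrinkage: float = 0.1,
                  n_boot: int = 100, seed: int = 0,
                  odin_config: OdinConfig | None = None) -> pd.DataFrame:
    """Evaluate the admissible method × metric cells on one dataset.

    Returns a tidy table with one row per (method, metric): inlier
    macro-AUC, per-outlier-class AUCs, the class-balanced pooled
    near-OOD AUC (bootstrap mean and sd), and the far-OOD AUC. OE
    methods expose ``exposure_n`` outliers per near-OOD class. A
    requested pair outside the admissibility matrix raises.
    """
    methods = list(methods or METHODS)
    for m in methods:
        if m not in ADMISSIBLE:
            raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
        if metrics is not None:
            bad = [x for x in metrics if x not in ADMISSIBLE[m]]
            if bad:
                raise ValueError(
                    f"method {m!r} does not admit metrics {bad}; the "
                    f"admissible pairs are octood.benchmark.ADMISSIBLE")
    tcfg = train_config or TrainConfig.desk_scale()
    boot_seed = derive_seed(seed, "bootstrap")

    cache: dict[str, CompactNet] = {}

    def base_softmax() -> CompactNet:
        if "softmax" not in cache:
            cache["softmax"] = _fit(dataset, "softmax", tcfg,
                                    derive_seed(seed, "softmax"))
        return cache["softmax"]

    rows: list[dict] = []
    for method in methods:
        use_metrics = list(metrics) if metrics is not None else list(ADMISSIBLE[method])
        use_metrics = [x for x in use_metrics if x in ADMISSIBLE[method]]
        base_row = {"method": method, "seed": seed,
                    "n_exposed": exposure_n if method in _OE_METHODS else 0,
                    "exposed_classes": "+".join(NEAR_OOD_CLASSES)
                    if method in _OE_METHODS else ""}
        kw = {}
        if method in ("softmax", "mc_dropout", "tta"):
            model = base_softmax()
        elif method == "ensemble":
            members = [
                _fit(dataset, "softmax", tcfg, derive_seed(seed, "ensemble", i))
                for i in range(ensemble_size)]
            model, kw = members[0], {"ensemble": members}
        elif method in ("temp_scaling", "odin"):
            model = base_softmax()
            val_in = dataset.val.by_role("inlier").pixels
            val_ood = _validation_ood(dataset, derive_seed(seed, "odin-val"))
            ocfg = odin_config or OdinConfig()
            if method == "temp_scaling":
                ocfg = OdinConfig(temperatures=ocfg.temperatures, epsilons=(0.0,))
            T, eps = odin_grid_search(model, val_in, val_ood, ocfg)
            kw = {"T": T, "eps": eps}
            base_row.update(odin_T=T, odin_eps=eps)
        elif method == "dirichlet":
            model = _fit(dataset, "dirichlet", tcfg, derive_seed(seed, method))
        elif method in _OE_METHODS:
            exp = ExposureConfig(classes=NEAR_OOD_CLASSES,
                                 n_per_class=exposure_n, replicate=0)
            model = _fit(dataset, _HEAD_OF.get(method, "softmax"), tcfg,
                         derive_seed(seed, method), exposure=exp)
        else:  # pragma: no cover
            raise AssertionError(method)

        scorer = _ModelScorer(method, model, dataset, shrinkage,
                              seed=derive_seed(seed, method, "scorer"),
                              n_repeats=n_repeats, **kw)
        rows.extend(_evaluate(scorer, dataset, use_metrics, n_boot,
                              boot_seed, base_row))
    return pd.DataFrame(rows)


def score_test_set(dataset: SplitDataset, method: str, metrics=None,
                   train_config: TrainConfig | None = None,
                   exposure_n: int = 4, shrinkage: float = 0.1,
                   n_repeats: int = 20, seed: int = 0) -> pd.DataFrame:
    """Per-sample OOD scores for one method on the test split, as a tidy
    table with columns (sample_id, label, role, method, metric, score);
    writable with :func:`octood.io.write_scores_csv`."""
    if method not in ADMISSIBLE:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    metrics = list(metrics or ADMISSIBLE[method])
    bad = [m for m in metrics if m not in ADMISSIBLE[method]]
    if bad:
        raise ValueError(f"method {method!r} does not admit metrics {bad}")
    tcfg = train_config or TrainConfig.desk_scale()
    kw = {}
    if method in ("ensemble",):
        raise ValueError("per-sample scoring for ensembles is not supported; "
                         "use run_benchmark")
    exposure = (ExposureConfig(classes=NEAR_OOD_CLASSES, n_per_class=exposure_n)
                if method in _OE_METHODS else None)
    model = _fit(dataset, _HEAD_OF.get(method, "softmax"), tcfg,
                 derive_seed(seed, method), exposure=exposure)
    if method in ("temp_scaling", "odin"):
        val_in = dataset.val.by_role("inlier").pixels
        val_ood = _validation_ood(dataset, derive_seed(seed, "odin-val"))
        ocfg = OdinConfig() if method == "odin" else OdinConfig(epsilons=(0.0,))
        T, eps = odin_grid_search(model, val_in, val_ood, ocfg)
        kw = {"T": T, "eps": eps}
    scorer = _ModelScorer(method, model, dataset, shrinkage,
                          seed=derive_seed(seed, method, "scorer"),
                          n_repeats=n_repeats, **kw)
    test = dataset.test
    rows = []
    for metric in metrics:
        s = scorer.scores(metric, test.pixels)
        for i in range(len(test)):
            rows.append({"sample_id": f"{test.subject_ids[i]}_{i:05d}",
                         "label": test.labels[i], "role": test.roles[i],
                         "method": method, "metric": metric,
                         "score": float(s[i])})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# few-shot exposure sweep
# ----------------------------------------------------------------------

_SWEEP_METRICS = {"softmax_oe_ent": ("entropy", "cosine"),
                  "dirichlet_oe_ent": ("entropy", "cosine"),
                  "softmax_oe_rb": ("rbp", "cosine", "entropy")}


def run_fewshot_sweep(dataset: SplitDataset, methods=("softmax_oe_ent", "softmax_oe_rb"),
                      class_sets=None, n_values=(1, 2, 4, 8, 16),
                      replicates: int = 5,
                      train_config: TrainConfig | None = None,
                      shrinkage: float = 0.1, n_boot: int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """Few-shot OE sweep: one row per (method, exposed-class set, n,
    replicate), with metric-specific AUC columns and the cosine distance
    of each outlier cluster center to the pooled inlier center.

    Replicates share the inlier training stream and differ only in the
    exposed outlier subset (disjoint across replicates). ``n = 0`` rows
    fall back to the corresponding no-exposure model.
    """
    if class_sets is None:
        class_sets = [("DME",), ("RVO",), ("Stargardt",), NEAR_OOD_CLASSES]
    tcfg = train_config or TrainConfig.desk_scale()
    boot_seed = derive_seed(seed, "bootstrap")
    test_in, near, far = _test_parts(dataset)
    probs_labels = _class_indices(test_in.labels)

    rows = []
    for method in methods:
        if method not in _OE_METHODS:
            raise ValueError(f"{method!r} is not an outlier-exposure method")
        head = _HEAD_OF.get(method, "softmax")
        for cset in class_sets:
            cset = tuple(cset)
            for n in n_values:
                train_seed = derive_seed(seed, method, cset, n)
                for rep in range(replicates):
                    if n == 0:
                        model = _fit(dataset, "softmax" if head != "dirichlet"
                                     else "dirichlet", tcfg, train_seed)
                        used_metrics = tuple(m for m in _SWEEP_METRICS[method]
                                             if m != "rbp")
                    else:
                        exp = ExposureConfig(classes=cset, n_per_class=n,
                                             replicate=rep)
                        model = _fit(dataset, head, tcfg, train_seed,
                                     exposure=exp)
                        used_metrics = _SWEEP_METRICS[method]
                    scorer = _ModelScorer(method if n else "softmax", model,
                                          dataset, shrinkage,
                                          seed=derive_seed(seed, method, rep))
                    row = {"method": method, "exposed_classes": "+".join(cset),
                           "n_exposed": n, "replicate": rep, "seed": seed}
                    row["macro_auc"] = macro_auc(
                        scorer.classification_probs(test_in.pixels), probs_labels)
                    for metric in used_metrics:
                        s_in = scorer.scores(metric, test_in.pixels)
                        per_class = {c: scorer.scores(metric, s.pixels)
                                     for c, s in near.items()}
                        for c, s in per_class.items():
                            row[f"auc_{c}_{metric}"] = auc(s_in, s)
                        mean, sd = balanced_bootstrap_auc(
                            s_in, per_class, n_boot=n_boot, seed=boot_seed)
                        row[f"near_auc_{metric}"] = mean
                        row[f"near_sd_{metric}"] = sd
                        if len(far):
                            row[f"far_auc_{metric}"] = auc(
                                s_in, scorer.scores(metric, far.pixels))
                    feats = extract_features(model, dataset.test.pixels)
                    keep = dataset.test.roles != "farOOD"
                    dists = cluster_cosine_distances(feats[keep],
                                                     dataset.test.labels[keep])
                    for c, d in dists.items():
                        row[f"center_dist_{c}"] = d
                    rows.append(row)
                    if n == 0:
                        break  # no replicate variation without exposure
    return pd.DataFrame(rows)
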