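"""Desk-scale reproduction study.

Runs the full qualitative protocol on synthetic data, repeated over
several seeds, and summarizes the directional findings the framework is
built to probe:

* inlier classification stays at ceiling with and without outlier
  exposure (OE);
* far-OOD detection is easier than near-OOD detection for the cosine
  feature-space metric, for every method that admits it;
* reject-bucket OE with a handful of exposed outliers per class lifts
  the balanced near-OOD cosine AUC over the no-OE baseline;
* more exposed outliers help (the few-shot sweep), and exposure pushes
  the exposed classes' feature clusters away from the inlier centroid;
* exposing only the atrophy-like class does not help detect the
  fluid-bearing classes (class specificity of OE).

The heavy lifting is delegated to :mod:`octood.benchmark`; this module
just fixes the protocol (which models, which metrics, which
comparisons) and averages over seeds.
"""

from __future__ import annotations

import numpy as np

from .benchmark import _fit, _ModelScorer, _test_parts, _class_indices, derive_seed
from .evalstats import auc, balanced_bootstrap_auc, cluster_cosine_distances, macro_auc
from .nets import extract_features
from .odin import OdinConfig, odin_grid_search
from .synthgen import NEAR_OOD_CLASSES, DatasetConfig, generate_dataset
from .train import ExposureConfig, TrainConfig

__all__ = ["run_directional_study"]

_COSINE_METHODS = ("softmax", "dirichlet", "temp_scaling", "odin",
                   "softmax_oe_ent", "softmax_oe_rb", "dirichlet_oe_ent")


def _mean(rows: list[dict], key: str) -> float:
    vals = [r[key] for r in rows if key in r and np.isfinite(r[key])]
    return float(np.mean(vals))


def run_directional_study(master_seed: int = 1, n_seeds: int = 5,
                          images_per_class: int = 200,
                          n_exposed: int = 8,
                          n_values: tuple[int, ...] = (1, 2, 4, 8, 16),
                          train_config: TrainConfig | None = None,
                          n_boot: int = 100, shrinkage: float = 0.1,
                          verbose: bool = False) -> dict:
    """Run the protocol over ``n_seeds`` independent seeds and return
    per-seed rows plus seed-averaged summary numbers (see the keys of
    the returned ``summary`` dict)."""
    tcfg0 = train_config or TrainConfig.desk_scale()
    rows: list[dict] = []
    for i in range(n_seeds):
        seed = derive_seed(master_seed, "study", i)
        row = _one_seed(seed, images_per_class, n_exposed, n_values,
                        tcfg0, n_boot, shrinkage)
        rows.append(row)
        if verbose:
            print(f"[study] seed {i + 1}/{n_seeds} done")

    summary: dict[str, float] = {}
    for key in rows[0]:
        summary[key] = _mean(rows, key)
    # headline directional quantities
    summary["oe_rb_cosine_gain"] = (summary[f"near_cosine_oe_rb_n{n_exposed}"]
                                    - summary["near_cosine_softmax"])
    summary["stargardt_to_dme_gain"] = (summary["dme_entropy_oe_ent_stargardt"]
                                        - summary["dme_entropy_softmax"])
    summary["center_dist_shift"] = (summary[f"center_dist_n{max(n_values)}"]
                                    - summary[f"center_dist_n{min(n_values)}"])
    return {"per_seed": rows, "summary": summary}


def _one_seed(seed: int, images_per_class: int, n_exposed: int,
              n_values, tcfg0: TrainConfig, n_boot: int,
              shrinkage: float) -> dict:
    ds = generate_dataset(DatasetConfig(images_per_class=images_per_class,
                                        seed=derive_seed(seed, "data")))
    test_in, near, far = _test_parts(ds)
    yte = _class_indices(test_in.labels)
    boot_seed = derive_seed(seed, "boot")
    row: dict[str, float] = {}

    def evaluate(scorer: _ModelScorer, metric: str, prefix: str,
                 per_class_prefix: str | None = None):
        s_in = scorer.scores(metric, test_in.pixels)
        per_class = {c: scorer.scores(metric, s.pixels) for c, s in near.items()}
        mean, _ = balanced_bootstrap_auc(s_in, per_class, n_boot=n_boot,
                                         seed=boot_seed)
        row[f"near_{prefix}"] = mean
        row[f"far_{prefix}"] = auc(s_in, scorer.scores(metric, far.pixels))
        if per_class_prefix is not None:
            for c, s in per_class.items():
                row[f"{per_class_prefix}_{c}"] = auc(s_in, s)

    def fit(head, key, exposure=None):
        return _fit(ds, head, tcfg0, derive_seed(seed, key), exposure=exposure)

    # --- no-OE baselines ------------------------------------------------
    base = fit("softmax", "softmax")
    sc = _ModelScorer("softmax", base, ds, shrinkage, seed=derive_seed(seed, "sc"))
    row["macro_softmax"] = macro_auc(sc.classification_probs(test_in.pixels), yte)
    evaluate(sc, "cosine", "cosine_softmax")
    s_in = sc.scores("entropy", test_in.pixels)
    row["near_entropy_softmax"], _ = balanced_bootstrap_auc(
        s_in, {c: sc.scores("entropy", s.pixels) for c, s in near.items()},
        n_boot=n_boot, seed=boot_seed)
    row["dme_entropy_softmax"] = auc(s_in, sc.scores("entropy", near["DME"].pixels))

    diri = fit("dirichlet", "dirichlet")
    scd = _ModelScorer("dirichlet", diri, ds, shrinkage,
                       seed=derive_seed(seed, "scd"))
    row["macro_dirichlet"] = macro_auc(scd.classification_probs(test_in.pixels), yte)
    evaluate(scd, "cosine", "cosine_dirichlet")

    # temperature scaling and ODIN reuse the softmax backbone
    from .benchmark import _validation_ood
    val_in = ds.val.by_role("inlier").pixels
    val_ood = _validation_ood(ds, derive_seed(seed, "odin-val"))
    ocfg = OdinConfig()
    T_ts, _ = odin_grid_search(base, val_in, val_ood,
                               OdinConfig(temperatures=ocfg.temperatures,
                                          epsilons=(0.0,)))
    sct = _ModelScorer("temp_scaling", base, ds, shrinkage,
                       seed=derive_seed(seed, "sct"), T=T_ts, eps=0.0)
    evaluate(sct, "cosine", "cosine_temp_scaling")
    T_od, eps_od = odin_grid_search(base, val_in, val_ood, ocfg)
    sco = _ModelScorer("odin", base, ds, shrinkage,
                       seed=derive_seed(seed, "sco"), T=T_od, eps=eps_od)
    evaluate(sco, "cosine", "cosine_odin")
    row["odin_T"], row["odin_eps"] = T_od, eps_od

    # --- OE variants at n_exposed per class -----------------------------
    exp_all = ExposureConfig(classes=NEAR_OOD_CLASSES, n_per_class=n_exposed)
    oe_ent = fit("softmax", "oe_ent", exposure=exp_all)
    sce = _ModelScorer("softmax_oe_ent", oe_ent, ds, shrinkage,
                       seed=derive_seed(seed, "sce"))
    row["macro_oe_ent"] = macro_auc(sce.classification_probs(test_in.pixels), yte)
    evaluate(sce, "cosine", "cosine_softmax_oe_ent")

    diri_oe = fit("dirichlet", "diri_oe_ent", exposure=exp_all)
    scde = _ModelScorer("dirichlet_oe_ent", diri_oe, ds, shrinkage,
                        seed=derive_seed(seed, "scde"))
    row["macro_dirichlet_oe_ent"] = macro_auc(
        scde.classification_probs(test_in.pixels), yte)
    evaluate(scde, "cosine", "cosine_dirichlet_oe_ent")

    # class-specificity probe: expose only the atrophy-like class
    exp_st = ExposureConfig(classes=("Stargardt",), n_per_class=n_exposed)
    oe_st = fit("softmax", "oe_ent_stargardt", exposure=exp_st)
    scs = _ModelScorer("softmax_oe_ent", oe_st, ds, shrinkage,
                       seed=derive_seed(seed, "scs"))
    row["macro_oe_ent_stargardt"] = macro_auc(
        scs.classification_probs(test_in.pixels), yte)
    s_in = scs.scores("entropy", test_in.pixels)
    row["dme_entropy_oe_ent_stargardt"] = auc(
        s_in, scs.scores("entropy", near["DME"].pixels))

    # --- reject-bucket few-shot sweep -----------------------------------
    for n in n_values:
        exp = ExposureConfig(classes=NEAR_OOD_CLASSES, n_per_class=n)
        rb = fit("reject_bucket", f"oe_rb_n{n}", exposure=exp)
        scr = _ModelScorer("softmax_oe_rb", rb, ds, shrinkage,
                           seed=derive_seed(seed, "scr", n))
        if n == n_exposed:
            row["macro_oe_rb"] = macro_auc(
                scr.classification_probs(test_in.pixels), yte)
            evaluate(scr, "rbp", "rbp_oe_rb", per_class_prefix="rbp_oe_rb")
            evaluate(scr, "cosine", f"cosine_oe_rb_n{n}",
                     per_class_prefix="cosine_oe_rb")
        else:
            evaluate(scr, "cosine", f"cosine_oe_rb_n{n}")
        feats = extract_features(rb, ds.test.pixels)
        keep = ds.test.roles != "farOOD"
        dists = cluster_cosine_distances(feats[keep], ds.test.labels[keep])
        row[f"center_dist_n{n}"] = float(np.mean([dists[c] for c in NEAR_OOD_CLASSES]))
    return row
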