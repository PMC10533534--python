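"""File I/O: datasets as 8-bit grayscale PNGs with a CSV manifest and a
YAML config; model checkpoints as ``.npz`` weights with a JSON sidecar;
tidy score tables as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .nets import CompactNet
from .synthgen import DatasetConfig, ImageSet, SplitDataset

__all__ = ["save_dataset", "load_dataset", "save_model", "load_model",
           "write_scores_csv"]


def save_dataset(dataset: SplitDataset, outdir: str | Path) -> Path:
    """Write PNGs (one subdir per split), manifest.csv (path, label,
    role, subject_id, split) and config.yaml. Deterministic layout."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for split, iset in dataset.splits.items():
        d = out / split
        d.mkdir(exist_ok=True)
        for i in range(len(iset)):
            rel = f"{split}/{iset.labels[i]}_{iset.subject_ids[i]}_{i:05d}.png"
            arr = np.round(iset.pixels[i] * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / rel)
            records.append({"path": rel, "label": iset.labels[i],
                            "role": iset.roles[i],
                            "subject_id": iset.subject_ids[i], "split": split})
    pd.DataFrame(records).to_csv(out / "manifest.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return out


def load_dataset(indir: str | Path) -> SplitDataset:
    """Inverse of :func:`save_dataset` (8-bit quantization is lossy)."""
    ind = Path(indir)
    manifest = pd.read_csv(ind / "manifest.csv")
    with open(ind / "config.yaml") as fh:
        cfg = DatasetConfig.from_dict(yaml.safe_load(fh))
    sets = {}
    for split in ("train", "val", "test", "pool"):
        df = manifest[manifest["split"] == split]
        if len(df) == 0:
            sets[split] = ImageSet.empty(cfg.side)
            continue
        pixels = np.stack([
            np.asarray(Image.open(ind / p), dtype=float) / 255.0
            for p in df["path"]])
        sets[split] = ImageSet(pixels,
                               df["label"].to_numpy(dtype=object),
                               df["role"].to_numpy(dtype=object),
                               df["subject_id"].to_numpy(dtype=object))
    return SplitDataset(config=cfg, **sets)


def save_model(model: CompactNet, path: str | Path) -> None:
    """Weights to ``<path>.npz``; head type / K / D / class names to a
    JSON sidecar ``<path>.json``."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params,
             _in_mu=model.in_mu, _in_proj=model.in_proj)
    from .synthgen import INLIER_CLASSES
    meta = dict(model.config, classes=list(INLIER_CLASSES[:model.K]))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> CompactNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    meta.pop("classes", None)
    model = CompactNet(**meta)
    with np.load(path.with_suffix(".npz")) as data:
        model.params = {k: data[k].copy() for k in data.files
                        if not k.startswith("_")}
        model.in_mu = data["_in_mu"].copy()
        model.in_proj = data["_in_proj"].copy()
    return model


def write_scores_csv(rows: pd.DataFrame, path: str | Path) -> None:
    """Tidy per-sample score table (sample_id, true label, role, method,
    metric, score) in a bit-stable CSV dialect (comma, UTF-8, '.')."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False, encoding="utf-8")
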